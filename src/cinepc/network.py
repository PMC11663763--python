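"""Dual-encoder 2D+time U-Net for joint banding/flow artifact suppression.

Two phase-cycled magnitude movies enter two encoder branches that share one
set of weights; their feature maps are fused (channel concatenation) at
every resolution level and decoded to a single artifact-suppressed movie.
The network is residual around the two-movie average — the untrained model
reproduces the 2P average baseline exactly — and inference is symmetrized
over the input order,

    output(p1, p2) = (network(p1, p2) + network(p2, p1)) / 2,

so the reconstruction is order-invariant by construction for any weights.
Spatial resolution halves per level; the temporal dimension is never
downsampled.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .phantom import CineMeta, CineMovie

__all__ = ["NetConfig", "TrainConfig", "DualEncoderUNet", "build_network",
           "normalize", "symmetrized_inference", "train",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class NetConfig:
    """Architecture hyper-parameters.

    Channel width doubles per level from ``base_channels``; each level is a
    pair of 3×3×3 conv + group-norm + ReLU layers.  The defaults give a
    compact model (~10^5 parameters) that trains in minutes on one CPU.
    """

    n_levels: int = 3
    base_channels: int = 16

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("need at least 2 levels")
        if self.base_channels < 1:
            raise ValueError("base_channels must be positive")

    @property
    def channels(self) -> list[int]:
        return [self.base_channels * 2 ** l for l in range(self.n_levels)]


@dataclass
class TrainConfig:
    """Optimization hyper-parameters (mean-absolute-error loss, Adam)."""

    lr: float = 2e-4
    steps: int = 600
    batch: int = 2
    crop: tuple[int, int, int] = (6, 32, 32)  # (t, y, x)
    val_fraction: float = 0.2
    augment: bool = True
    seed: int = 0
    eval_every: int = 50

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if not (0 <= self.val_fraction < 1):
            raise ValueError("val_fraction must be in [0, 1)")


class DualEncoderUNet:
    """Shared-weight dual-encoder U-Net over (t, y, x) magnitude movies.

    The encoder is a single stack of ConvBlocks applied to each input in
    turn (structural weight sharing: the two branches are the same layer
    objects), with spatial 2× average pooling between levels.  At every
    level the two branches' features are concatenated and fed to the
    decoder through skip connections; the zero-initialized final 1×1×1
    convolution makes the untrained output exactly (p1+p2)/2.
    """

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.channels
        L = config.n_levels
        self.enc = [nn.ConvBlock(1 if l == 0 else ch[l - 1], ch[l], rng)
                    for l in range(L)]
        self.bottleneck = nn.ConvBlock(2 * ch[-1], ch[-1], rng)
        # decoder level l consumes upsampled ch[l+1] (or bottleneck ch[L-1])
        # plus the fused skip 2*ch[l]
        self.dec = [nn.ConvBlock(ch[min(l + 1, L - 1)] + 2 * ch[l], ch[l], rng)
                    for l in range(L - 1)]
        self.head = nn.Conv3d(ch[0], 1, 1, rng, zero_init=True)

    # -- parameters -------------------------------------------------------
    def params(self) -> list:
        ps = []
        for b in self.enc:
            ps += b.params()
        ps += self.bottleneck.params()
        for b in self.dec:
            ps += b.params()
        ps += self.head.params()
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.v.size for p in self.params()))

    # -- forward/backward -------------------------------------------------
    def _encode(self, x: np.ndarray):
        feats, caches = [], []
        h = x
        for l, block in enumerate(self.enc):
            if l > 0:
                h = nn.avgpool2(h)
            h, c = block.forward(h)
            feats.append(h)
            caches.append(c)
        return feats, caches

    def _decode_backward_encoder(self, caches, gfeats):
        """Backprop one encoder pass given gradients w.r.t. its features."""
        g = None
        for l in reversed(range(len(self.enc))):
            gl = gfeats[l] if g is None else gfeats[l] + g
            g = self.enc[l].backward(caches[l], gl)
            if l > 0:
                g = nn.avgpool2_backward(g)
        return g

    def forward(self, x1: np.ndarray, x2: np.ndarray):
        """One (non-symmetrized) pass.  Inputs (B, 1, T, H, W), H, W
        divisible by 2^(n_levels-1).  Returns (out, cache)."""
        f1, c1 = self._encode(x1)
        f2, c2 = self._encode(x2)
        fused = [np.concatenate([a, b], axis=1) for a, b in zip(f1, f2)]
        d, cb = self.bottleneck.forward(fused[-1])
        dec_caches = []
        for l in reversed(range(len(self.dec))):
            up = nn.upsample2(d)
            cat = np.concatenate([up, fused[l]], axis=1)
            d, c = self.dec[l].forward(cat)
            dec_caches.append((c, up.shape[1]))
        corr, ch = self.head.forward(d)
        base = 0.5 * (x1 + x2)
        pre = base + corr
        out = np.maximum(pre, 0.0)
        cache = (c1, c2, cb, dec_caches, ch, pre > 0, [f.shape for f in fused])
        return out.astype(np.float32), cache

    def backward(self, cache, gout: np.ndarray) -> None:
        """Accumulate parameter gradients; input gradients are discarded."""
        c1, c2, cb, dec_caches, ch, posmask, fused_shapes = cache
        g = gout * posmask
        g = self.head.backward(ch, g)
        gfused = [np.zeros(s, dtype=np.float32) for s in fused_shapes]
        gd = g
        # walk decoder levels shallow -> deep (reverse of the forward order;
        # dec_caches were appended deepest-first)
        for l in range(len(self.dec)):
            c, up_ch = dec_caches[-(l + 1)]  # level l was appended last for l=0
            gcat = self.dec[l].backward(c, gd)
            gup, gskip = gcat[:, :up_ch], gcat[:, up_ch:]
            gfused[l] += gskip
            gd = nn.upsample2_backward(gup)
            # gd now feeds the next deeper level's output
        gb = self.bottleneck.backward(cb, gd)
        gfused[-1] += gb
        half = [s[1] // 2 for s in fused_shapes]
        g1 = [gf[:, :h] for gf, h in zip(gfused, half)]
        g2 = [gf[:, h:] for gf, h in zip(gfused, half)]
        self._decode_backward_encoder(c1, g1)
        self._decode_backward_encoder(c2, g2)

    # -- geometry-safe prediction -----------------------------------------
    def predict(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        """Forward pass with reflective padding to a legal spatial size and
        cropping back, so output geometry always equals input geometry."""
        div = 2 ** (self.config.n_levels - 1)
        T, H, W = x1.shape[-3:]
        ph, pw = (-H) % div, (-W) % div
        xp1, xp2 = x1, x2
        if ph or pw:
            pad = ((0, 0), (0, 0), (0, 0), (0, ph), (0, pw))
            xp1 = np.pad(x1, pad, mode="reflect")
            xp2 = np.pad(x2, pad, mode="reflect")
        out, _ = self.forward(xp1.astype(np.float32), xp2.astype(np.float32))
        return out[..., :H, :W]


def build_network(config: NetConfig | None = None, seed: int = 0) -> DualEncoderUNet:
    """Construct a dual-encoder U-Net with structurally shared encoders."""
    return DualEncoderUNet(config or NetConfig(), seed=seed)


def normalize(p1, p2):
    """Scale two movies by one shared factor (99th percentile of their
    pooled voxels), preserving the inter-movie intensity relationship that
    encodes the banding.  Returns (scaled p1, scaled p2, factor)."""
    a = p1.data if isinstance(p1, CineMovie) else np.asarray(p1)
    b = p2.data if isinstance(p2, CineMovie) else np.asarray(p2)
    factor = float(np.percentile(np.concatenate([a.ravel(), b.ravel()]), 99.0))
    if factor <= 0:
        warnings.warn("all-zero input movies; normalization is a no-op")
        factor = 1.0
    return (a / factor).astype(np.float32), (b / factor).astype(np.float32), factor


def symmetrized_inference(model: DualEncoderUNet, p1, p2) -> CineMovie:
    """Order-invariant reconstruction: average of both input orderings."""
    a = p1.data if isinstance(p1, CineMovie) else np.asarray(p1)
    b = p2.data if isinstance(p2, CineMovie) else np.asarray(p2)
    if a.shape != b.shape:
        raise ValueError(f"geometry mismatch: {a.shape} vs {b.shape}")
    an, bn, factor = normalize(a, b)
    x1 = an[None, None]
    x2 = bn[None, None]
    y = 0.5 * (model.predict(x1, x2) + model.predict(x2, x1))
    out = np.maximum(y[0, 0] * factor, 0.0).astype(np.float32)
    if isinstance(p1, CineMovie):
        meta = CineMeta(**{**p1.meta.to_dict(), "kind": "network"})
        return CineMovie(out, meta)
    return CineMovie(out, CineMeta(psi_deg=0.0, tr_ms=1.0, te_ms=0.5,
                                   flip_deg=60.0, frame_duration_ms=1.0,
                                   kind="network"))


def _as_array(m) -> np.ndarray:
    return m.data if isinstance(m, CineMovie) else np.asarray(m, dtype=np.float32)


def train(model: DualEncoderUNet, dataset, cfg: TrainConfig | None = None):
    """Seeded mini-batch training on (p1, p2, label) triples.

    Random spatiotemporal crops, optional flips, and per-sample input-order
    randomization (the stochastic counterpart of symmetrized inference);
    each crop pair is normalized by its shared factor and the label by the
    same factor; the loss is the mean absolute error.  Returns
    ``(model, history)`` with per-step training loss and periodic
    validation loss on held-out scenes.
    """
    cfg = cfg or TrainConfig()
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    triples = [(_as_array(a), _as_array(b), _as_array(y)) for a, b, y in dataset]
    for a, b, y in triples:
        if not (a.shape == b.shape == y.shape):
            raise ValueError("each (p1, p2, label) triple must share geometry")

    rng = np.random.default_rng(cfg.seed)
    n_val = int(round(cfg.val_fraction * len(triples)))
    order = rng.permutation(len(triples))
    val_idx = order[:n_val]
    train_idx = order[n_val:] if n_val < len(triples) else order
    opt = nn.Adam(model.params(), lr=cfg.lr)
    ct, ch, cw = cfg.crop

    def sample_crop(idx):
        a, b, y = triples[idx]
        T, H, W = a.shape
        t0 = rng.integers(0, max(T - ct, 0) + 1)
        y0 = rng.integers(0, max(H - ch, 0) + 1)
        x0 = rng.integers(0, max(W - cw, 0) + 1)
        sl = (slice(t0, t0 + ct), slice(y0, y0 + ch), slice(x0, x0 + cw))
        pa, pb, py = a[sl], b[sl], y[sl]
        if cfg.augment:
            if rng.random() < 0.5:
                pa, pb, py = pa[:, ::-1], pb[:, ::-1], py[:, ::-1]
            if rng.random() < 0.5:
                pa, pb, py = pa[:, :, ::-1], pb[:, :, ::-1], py[:, :, ::-1]
            if rng.random() < 0.5:
                pa, pb = pb, pa
        return pa, pb, py

    def make_batch(indices):
        x1, x2, yy = [], [], []
        for i in indices:
            pa, pb, py = sample_crop(i)
            a_n, b_n, f = normalize(pa, pb)
            x1.append(a_n)
            x2.append(b_n)
            yy.append((py / f).astype(np.float32))
        return (np.stack(x1)[:, None], np.stack(x2)[:, None],
                np.stack(yy)[:, None])

    def val_loss():
        if len(val_idx) == 0:
            return float("nan")
        losses = []
        for i in val_idx:
            a, b, y = triples[i]
            an, bn, f = normalize(a, b)
            pred = model.predict(an[None, None], bn[None, None])
            losses.append(float(np.mean(np.abs(pred[0, 0] - y / f))))
        return float(np.mean(losses))

    history = {"loss": [], "val_loss": [], "val_step": []}
    for step in range(cfg.steps):
        idx = rng.choice(train_idx, size=cfg.batch, replace=True)
        x1, x2, y = make_batch(idx)
        out, cache = model.forward(x1, x2)
        resid = out - y
        loss = float(np.mean(np.abs(resid)))
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss at step {step}; lower the learning rate")
        history["loss"].append(loss)
        gout = (np.sign(resid) / resid.size).astype(np.float32)
        opt.zero_grad()
        model.backward(cache, gout)
        opt.step()
        if (step + 1) % cfg.eval_every == 0 or step == cfg.steps - 1:
            history["val_loss"].append(val_loss())
            history["val_step"].append(step + 1)
    return model, history


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path: str | os.PathLike, model: DualEncoderUNet,
                    train_cfg: TrainConfig | None = None,
                    seed: int | None = None) -> None:
    """Serialize weights + configuration to a single .npz file."""
    arrays = {f"p{i}": p.v for i, p in enumerate(model.params())}
    meta = {"net": asdict(model.config),
            "train": asdict(train_cfg) if train_cfg else None,
            "seed": seed}
    tmp = f"{path}.tmp.npz"
    np.savez_compressed(tmp, _meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    os.replace(tmp, path)


def load_checkpoint(path: str | os.PathLike) -> DualEncoderUNet:
    with np.load(path) as z:
        meta = json.loads(bytes(z["_meta"]).decode())
        model = build_network(NetConfig(**meta["net"]))
        for i, p in enumerate(model.params()):
            p.v[...] = z[f"p{i}"]
    return model
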