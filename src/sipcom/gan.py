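"""3D patch-based conditional adversarial MRI->PET translation.

The generator is a 3D U-Net whose encoder/decoder stages are residual
units; the encoder downsamples with strided convolutions (channel widths
32, 64, 128, 256, 512 by default) and the decoder upsamples with transpose
convolutions (512, 256, 128, 64, 32), with skip connections at every
resolution.  The discriminator is a patch classifier conditioned on the
(T1w, PET) pair: five convolution stages with 64, 128, 256, 512 and 1
channels whose output is a real/fake score map.

Training alternates discriminator and generator Adam updates at a constant
learning rate on 32^3 voxel patches sampled inside the brain mask.  The
generator loss is the average of an L2 reconstruction term weighted by
lambda (default 200) and the adversarial term; the discriminator loss is
the average of its real and fake terms (the usual pix2pix halving).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .io_prep import BrainMask, Volume3D, check_same_lattice

__all__ = [
    "GanConfig",
    "GeneratorState",
    "build_models",
    "sample_patches",
    "train_gan",
    "predict_volume",
    "sliding_window_predict",
]


@dataclass(frozen=True)
class GanConfig:
    """Model and training hyper-parameters.

    Defaults are the full-scale settings (1000 epochs, 32^3 patches,
    channel widths up to 512); tests and examples pass much smaller
    channel/epoch values, which changes nothing structurally.
    """

    enc_channels: tuple[int, ...] = (32, 64, 128, 256, 512)
    dec_channels: tuple[int, ...] = (512, 256, 128, 64, 32)
    disc_channels: tuple[int, ...] = (64, 128, 256, 512, 1)
    patch_edge: int = 32
    lambda_mse: float = 200.0
    lr: float = 2e-4
    adam_betas: tuple[float, float] = (0.5, 0.999)
    epochs: int = 1000
    batch_size: int = 20
    patches_per_pair: int = 40
    adversarial: str = "bce"  # "bce" | "lsgan"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_mse < 0:
            raise ValueError("lambda_mse must be >= 0")
        if len(self.enc_channels) != len(self.dec_channels):
            raise ValueError("encoder and decoder must have equal depth")
        if self.adversarial not in ("bce", "lsgan"):
            raise ValueError("adversarial loss must be 'bce' or 'lsgan'")
        depth = len(self.enc_channels)
        if self.patch_edge % 2 ** (depth - 1) != 0:
            raise ValueError(
                f"patch edge {self.patch_edge} not divisible by "
                f"2^(depth-1) = {2 ** (depth - 1)}"
            )

    @property
    def depth(self) -> int:
        return len(self.enc_channels)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GanConfig":
        d = dict(d)
        for key in ("enc_channels", "dec_channels", "disc_channels", "adam_betas"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class Generator(nn.Module):
    """Residual 3D U-Net mapping a 1-channel T1w patch to a PET patch."""

    def __init__(self, config: GanConfig, rng: np.random.Generator):
        super().__init__()
        enc, dec = config.enc_channels, config.dec_channels
        self.depth = len(enc)
        self.encoders = []
        in_ch = 1
        for i, ch in enumerate(enc):
            unit = nn.ResidualUnit(in_ch, ch, stride=1 if i == 0 else 2, rng=rng)
            self.encoders.append(unit)
            self._modules[f"enc{i}"] = unit
            in_ch = ch
        self.ups = []
        self.decoders = []
        cur = enc[-1]
        for i in range(1, self.depth):
            out_ch = dec[i]
            up = nn.ConvTranspose3d(cur, out_ch, kernel=2, stride=2, rng=rng)
            unit = nn.ResidualUnit(out_ch + enc[self.depth - 1 - i], out_ch, rng=rng)
            self.ups.append(up)
            self.decoders.append(unit)
            self._modules[f"up{i}"] = up
            self._modules[f"dec{i}"] = unit
            cur = out_ch
        self.head = nn.Conv3d(cur, 1, kernel=1, padding=0, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        skips = []
        for unit in self.encoders:
            x = unit(x)
            skips.append(x)
        for up, unit, skip in zip(self.ups, self.decoders, reversed(skips[:-1])):
            x = unit(nn.concat(up(x), skip))
        return self.head(x).sigmoid()


class Discriminator(nn.Module):
    """Conditional patch discriminator on the stacked (T1w, PET) pair."""

    def __init__(self, config: GanConfig, rng: np.random.Generator):
        super().__init__()
        chans = config.disc_channels
        layers: list[nn.Module] = []
        in_ch = 2
        for i, ch in enumerate(chans[:-1]):
            layers.append(nn.Conv3d(in_ch, ch, 3, stride=2, rng=rng))
            if i > 0:  # no normalization on the first stage
                layers.append(nn.BatchNorm3d(ch))
            layers.append(nn.PReLU(ch))
            in_ch = ch
        layers.append(nn.Conv3d(in_ch, chans[-1], 3, stride=1, rng=rng))
        self.net = nn.Sequential(*layers)

    def forward(self, t1w: nn.Tensor, pet: nn.Tensor) -> nn.Tensor:
        return self.net(nn.concat(t1w, pet))


def build_models(config: GanConfig) -> tuple[Generator, Discriminator]:
    """Instantiate generator and discriminator from the config seed."""
    rng = np.random.default_rng(config.seed)
    return Generator(config, rng), Discriminator(config, rng)


@dataclass
class GeneratorState:
    """A trained generator: parameters + config + training metadata.

    Save/load round-trips bit-identically; predictions after a round trip
    equal predictions before it.
    """

    generator: Generator
    config: GanConfig
    metadata: dict = field(default_factory=dict)

    def predict_patch(self, t1w_patch: np.ndarray) -> np.ndarray:
        """Map one (edge^3) T1w patch to a PET patch (eval mode)."""
        self.generator.eval()
        x = nn.Tensor(t1w_patch[None, None])
        return self.generator(x).data[0, 0].astype(np.float64)

    def predict_volume(
        self, t1w: Volume3D, mask: BrainMask | None = None
    ) -> Volume3D:
        return predict_volume(self, t1w, mask)

    def save(self, path: str | Path) -> Path:
        """Write a single-archive checkpoint (parameters, config, metadata)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        buf = io.BytesIO()
        np.savez(buf, **self.generator.state_dict())
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("params.npz", buf.getvalue())
            zf.writestr("config.json", json.dumps(self.config.to_dict()))
            zf.writestr("metadata.json", json.dumps(self.metadata, default=str))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "GeneratorState":
        with zipfile.ZipFile(Path(path)) as zf:
            config = GanConfig.from_dict(json.loads(zf.read("config.json")))
            metadata = json.loads(zf.read("metadata.json"))
            with zf.open("params.npz") as fh:
                state = dict(np.load(io.BytesIO(fh.read())))
        generator, _ = build_models(config)
        generator.load_state_dict(state)
        generator.eval()
        return cls(generator=generator, config=config, metadata=metadata)


def sample_patches(
    t1w: Volume3D,
    pet: Volume3D,
    mask: BrainMask,
    n: int,
    patch_edge: int,
    seed: int | np.random.Generator = 0,
) -> list[tuple[np.ndarray, np.ndarray, tuple[int, int, int]]]:
    """Draw n paired patches with centers inside the brain mask.

    Both modalities are cropped at identical coordinates.  Returns
    (t1w_patch, pet_patch, start_index) triples; reproducible under seed.

    Raises
    ------
    ValueError
        If the volume is smaller than the patch in any dimension.
    """
    check_same_lattice(t1w, pet, mask)
    shape = np.array(t1w.shape)
    if np.any(shape < patch_edge):
        raise ValueError(
            f"volume {tuple(shape)} smaller than patch edge {patch_edge}"
        )
    if n == 0:
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = np.argwhere(mask.data)
    picks = centers[rng.integers(0, len(centers), size=n)]
    out = []
    half = patch_edge // 2
    for c in picks:
        start = np.clip(c - half, 0, shape - patch_edge)
        sl = tuple(slice(s, s + patch_edge) for s in start)
        out.append(
            (
                np.asarray(t1w.data[sl], dtype=np.float64),
                np.asarray(pet.data[sl], dtype=np.float64),
                tuple(int(s) for s in start),
            )
        )
    return out


def _adversarial_loss(logits: nn.Tensor, target: float, form: str) -> nn.Tensor:
    if form == "bce":
        return nn.bce_with_logits(logits, target)
    # least-squares variant on the raw score map
    return nn.mse_loss(logits, np.full(logits.shape, target, dtype=np.float32))


def train_gan(
    pairs: list[tuple[Volume3D, Volume3D, BrainMask]],
    config: GanConfig,
    progress: bool = False,
) -> tuple[GeneratorState, pd.DataFrame]:
    """Train the conditional model on paired (T1w, PET, mask) studies.

    Per epoch, ``patches_per_pair`` patches are sampled from every pair and
    visited in shuffled mini-batches; each batch does one discriminator and
    one generator Adam update.  Returns the trained state and a per-epoch
    loss history (columns: epoch, g_loss, g_mse, g_adv, d_loss).

    Raises
    ------
    RuntimeError
        If a non-finite loss is encountered.
    """
    if not pairs:
        raise ValueError("need at least one training pair")
    gen, disc = build_models(config)
    opt_g = nn.Adam(gen.parameters(), lr=config.lr, betas=config.adam_betas)
    opt_d = nn.Adam(disc.parameters(), lr=config.lr, betas=config.adam_betas)
    rng = np.random.default_rng((config.seed, 0xD1CE))
    history = []

    for epoch in range(config.epochs):
        batch_pool = []
        for t1w, pet, mask in pairs:
            batch_pool.extend(
                (a, b)
                for a, b, _ in sample_patches(
                    t1w, pet, mask, config.patches_per_pair, config.patch_edge, rng
                )
            )
        order = rng.permutation(len(batch_pool))
        sums = {"g_loss": 0.0, "g_mse": 0.0, "g_adv": 0.0, "d_loss": 0.0}
        n_batches = 0
        for b0 in range(0, len(order), config.batch_size):
            idx = order[b0 : b0 + config.batch_size]
            t1 = np.stack([batch_pool[i][0] for i in idx])[:, None]
            pt = np.stack([batch_pool[i][1] for i in idx])[:, None]
            t1_t = nn.Tensor(t1)
            gen.train()
            disc.train()

            fake = gen(t1_t)

            # discriminator update: real pair vs detached fake pair
            d_real = disc(nn.Tensor(t1), nn.Tensor(pt))
            d_fake = disc(nn.Tensor(t1), fake.detach())
            loss_d = 0.5 * (
                _adversarial_loss(d_real, 1.0, config.adversarial)
                + _adversarial_loss(d_fake, 0.0, config.adversarial)
            )
            opt_d.zero_grad()
            loss_d.backward()
            opt_d.step()

            # generator update: weighted reconstruction + adversarial
            d_fake_g = disc(nn.Tensor(t1), fake)
            g_mse = nn.mse_loss(fake, pt)
            g_adv = _adversarial_loss(d_fake_g, 1.0, config.adversarial)
            loss_g = 0.5 * (config.lambda_mse * g_mse + g_adv)
            opt_g.zero_grad()
            opt_d.zero_grad()  # discard D grads from the G pass
            loss_g.backward()
            opt_g.step()

            vals = {
                "g_loss": float(loss_g.data),
                "g_mse": float(g_mse.data),
                "g_adv": float(g_adv.data),
                "d_loss": float(loss_d.data),
            }
            if not all(np.isfinite(v) for v in vals.values()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: {vals}"
                )
            for k, v in vals.items():
                sums[k] += v
            n_batches += 1
        record = {"epoch": epoch, **{k: v / max(n_batches, 1) for k, v in sums.items()}}
        history.append(record)
        if progress:  # pragma: no cover
            print(
                f"epoch {epoch:4d}  G {record['g_loss']:.4f} "
                f"(mse {record['g_mse']:.5f})  D {record['d_loss']:.4f}"
            )

    hist = pd.DataFrame(history)
    state = GeneratorState(
        generator=gen.eval(),
        config=config,
        metadata={
            "epochs_run": config.epochs,
            "final_g_loss": float(hist.g_loss.iloc[-1]) if len(hist) else None,
            "final_d_loss": float(hist.d_loss.iloc[-1]) if len(hist) else None,
            "n_pairs": len(pairs),
        },
    )
    return state, hist


def _taper_1d(edge: int) -> np.ndarray:
    """Raised-cosine window, strictly positive so weights never vanish."""
    i = np.arange(edge)
    return 0.5 - 0.5 * np.cos(2 * np.pi * (i + 0.5) / edge) + 1e-2


def sliding_window_predict(
    fn,
    data: np.ndarray,
    window: int,
    overlap: float = 0.5,
    window_order: list[int] | None = None,
) -> np.ndarray:
    """Whole-volume inference by overlapped windows with tapered blending.

    ``fn`` maps a (window^3) array to a same-shape array.  Windows tile the
    reflect-padded volume with the given fractional overlap; each
    prediction is accumulated under a separable raised-cosine weight and
    the sum is normalized by the accumulated weight, which therefore sums
    to one at every voxel.  ``window_order`` permutes processing order
    (accumulation is commutative up to float round-off).
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    step = max(1, int(round(window * (1.0 - overlap))))
    shape = np.array(data.shape)
    padded_shape = np.maximum(shape, window)
    # extend so the last window is flush
    padded_shape = padded_shape + (-(padded_shape - window)) % step
    pad = [(0, int(p - s)) for s, p in zip(shape, padded_shape)]
    vol = np.pad(data.astype(np.float64), pad, mode="reflect")

    starts = [list(range(0, p - window + 1, step)) for p in padded_shape]
    coords = [
        (i, j, k) for i in starts[0] for j in starts[1] for k in starts[2]
    ]
    if window_order is not None:
        coords = [coords[i] for i in window_order]

    t = _taper_1d(window)
    weight = t[:, None, None] * t[None, :, None] * t[None, None, :]
    acc = np.zeros(vol.shape)
    wsum = np.zeros(vol.shape)
    for i, j, k in coords:
        sl = (slice(i, i + window), slice(j, j + window), slice(k, k + window))
        acc[sl] += weight * np.asarray(fn(vol[sl]), dtype=np.float64)
        wsum[sl] += weight
    out = acc / wsum
    return out[: shape[0], : shape[1], : shape[2]]


def predict_volume(
    state: GeneratorState,
    t1w: Volume3D,
    mask: BrainMask | None = None,
    overlap: float = 0.5,
) -> Volume3D:
    """Predict a whole pseudo-normal PET volume from a T1w volume.

    Sliding-window inference at the training patch size with 50% overlap
    and cosine-tapered blending; the output lies on the input lattice.
    When a mask is given, out-of-mask voxels are zeroed.
    """
    out = sliding_window_predict(
        state.predict_patch, np.asarray(t1w.data), state.config.patch_edge, overlap
    )
    if mask is not None:
        out = np.where(mask.data, out, 0.0)
    return Volume3D(out, t1w.affine, modality="pet_predicted")
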