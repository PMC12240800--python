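"""Autoencoder models (punctate and polymorphic) and the training loop.

The punctate model pairs the VN-DGCNN encoder with the folding decoder and
an earth mover's distance loss: the optimal matching is solved on values
(Hungarian), then gradients flow through the matched squared distances.
The polymorphic model pairs the encoder (on surface points) with the
implicit SDF decoder and a squared-error loss on clipped signed distances;
during training the decoder is conditioned on the flattened vector latent,
while analyses use the invariant norms extracted afterwards.

Training is plain seeded stochastic optimization with Adam, one sample per
step, with per-epoch resampling hooks (sparse subsampling / jitter) left to
the dataset callable.
"""

from __future__ import annotations

import hashlib
import io
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import autodiff as ad
from .emd import emd_match
from . import vn
from .autodiff import Adam, Tensor
from .decoders import FoldingDecoder, ImplicitSDFDecoder

__all__ = [
    "ModelConfig",
    "PointCloudAutoencoder",
    "SDFAutoencoder",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Hyperparameters for both model families.

    ``decoder`` selects the family: ``folding_plane`` / ``folding_sphere``
    pair with the EMD loss (punctate), ``implicit_sdf`` with the SDF
    squared-error loss (polymorphic).
    """

    bottleneck: int = 64
    hidden_channels: tuple = (16, 16, 16, 32, 32, 32)
    k_neighbors: int = 20
    alpha: float = 0.2
    input_dim: int = 3
    pool: str = "max"
    decoder: str = "folding_sphere"
    template_points: int = 256
    decoder_hidden: int = 64
    sdf_hidden_layers: int = 4
    grid_size: float = 32.0
    loss: str = "emd"
    lr: float = 1e-3
    epochs: int = 10
    seed: int = 0

    def __post_init__(self):
        folding = self.decoder in ("folding_plane", "folding_sphere")
        if folding != (self.loss == "emd"):
            raise ValueError(
                "decoder/loss pairing must be folding<->emd or "
                "implicit_sdf<->sdf_mse"
            )
        if not folding and self.decoder != "implicit_sdf":
            raise ValueError(f"unknown decoder {self.decoder!r}")

    @property
    def n_blocks(self):
        return len(self.hidden_channels)

    def config_hash(self) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


class PointCloudAutoencoder:
    """Rotation-invariant autoencoder for punctate point clouds."""

    def __init__(self, config: ModelConfig):
        if config.loss != "emd":
            raise ValueError("PointCloudAutoencoder requires the EMD loss")
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        enc_seed, dec_seed = (
            int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2)
        )
        self.encoder = vn.VNEncoder(
            bottleneck=config.bottleneck,
            hidden_channels=config.hidden_channels,
            k=config.k_neighbors,
            alpha=config.alpha,
            input_dim=config.input_dim,
            pool=config.pool,
            seed=enc_seed,
        )
        self.decoder = FoldingDecoder(
            rep_dim=config.bottleneck,
            template="sphere" if config.decoder == "folding_sphere" else "plane",
            m=config.template_points,
            out_dim=config.input_dim,
            hidden=config.decoder_hidden,
            seed=dec_seed,
        )

    @property
    def params(self):
        return self.encoder.params + self.decoder.params

    def encode(self, points) -> Tensor:
        return self.encoder(points)

    def representation(self, points) -> np.ndarray:
        """Rotation-invariant representation (numpy, length = bottleneck)."""
        return vn.invariant_representation(self.encode(points))

    def reconstruct(self, points, latent: Tensor | None = None) -> Tensor:
        """Reoriented reconstruction of an input cloud."""
        latent = self.encode(points) if latent is None else latent
        rep = vn.invariant_representation_t(latent)
        rotation = vn.rotation_from_latent(latent)
        return self.decoder(rep, rotation)

    def loss(self, points) -> Tensor:
        """EMD loss: optimal matching on values, squared error through it."""
        points = np.asarray(points, dtype=np.float64)
        recon = self.reconstruct(points)
        sigma = emd_match(recon.data, points)
        target = points[sigma]
        return ad.reduce_mean(
            ad.reduce_sum(ad.square(ad.sub(recon, target)), axis=1)
        )


class SDFAutoencoder:
    """Rotation-invariant autoencoder for polymorphic structures via SDF."""

    def __init__(self, config: ModelConfig):
        if config.decoder != "implicit_sdf":
            raise ValueError("SDFAutoencoder requires decoder='implicit_sdf'")
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        enc_seed, dec_seed = (
            int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2)
        )
        self.encoder = vn.VNEncoder(
            bottleneck=config.bottleneck,
            hidden_channels=config.hidden_channels,
            k=config.k_neighbors,
            alpha=config.alpha,
            input_dim=3,
            pool=config.pool,
            seed=enc_seed,
        )
        # trained on the flattened vector latent (orientation-aware);
        # invariant norms are taken after training for analysis
        self.decoder = ImplicitSDFDecoder(
            cond_dim=3 * config.bottleneck,
            hidden=config.decoder_hidden,
            n_hidden_layers=config.sdf_hidden_layers,
            grid_size=config.grid_size,
            seed=dec_seed,
        )

    @property
    def params(self):
        return self.encoder.params + self.decoder.params

    def encode(self, surface_points) -> Tensor:
        return self.encoder(surface_points)

    def representation(self, surface_points) -> np.ndarray:
        return vn.invariant_representation(self.encode(surface_points))

    def predict_sdf(self, surface_points, queries, latent=None) -> Tensor:
        latent = self.encode(surface_points) if latent is None else latent
        cond = ad.reshape(latent, (-1,))
        return self.decoder(cond, queries)

    def loss(self, sample) -> Tensor:
        """Mean squared error against clipped SDF targets.

        ``sample`` carries ``surface_points``, ``query_points`` and
        ``sdf_values`` (an :class:`morphocloud.sdf.SDFSamples`).
        """
        pred = self.predict_sdf(sample.surface_points, sample.query_points)
        return ad.reduce_mean(ad.square(ad.sub(pred, sample.sdf_values)))


def train(dataset, config: ModelConfig, model=None, callback=None):
    """Train an autoencoder over ``dataset``.

    ``dataset`` is a sequence; each element is either a point cloud array
    (EMD family) or an SDF sample (SDF family), or a callable taking an
    epoch-specific ``numpy.random.Generator`` and returning one — the hook
    used for per-epoch sparse resampling and jitter augmentation.

    Returns ``(model, log)`` where ``log`` is a list of per-epoch mean
    losses. Aborts with ``FloatingPointError`` if the loss goes non-finite.
    """
    if model is None:
        model = (
            SDFAutoencoder(config)
            if config.decoder == "implicit_sdf"
            else PointCloudAutoencoder(config)
        )
    opt = Adam(model.params, lr=config.lr)
    ss = np.random.SeedSequence([config.seed, 0xD1CE])
    log = []
    for epoch in range(config.epochs):
        rng = np.random.default_rng(ss.spawn(1)[0])
        order = rng.permutation(len(dataset))
        losses = []
        for idx in order:
            item = dataset[idx]
            if callable(item):
                item = item(rng)
            opt.zero_grad()
            loss = model.loss(item)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, sample {idx}"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        log.append(float(np.mean(losses)))
        if callback is not None:
            callback(epoch, log[-1])
    return model, log


def save_checkpoint(path, model, log=None, manifest_hash: str = ""):
    """Single-file checkpoint: weights (npz) + config (yaml) + metadata."""
    path = Path(path)
    buf = io.BytesIO()
    np.savez(buf, **{f"p{i}": p.data for i, p in enumerate(model.params)})
    with zipfile.ZipFile(path, "w") as z:
        z.writestr("weights.npz", buf.getvalue())
        z.writestr(
            "config.yaml", yaml.safe_dump(asdict(model.config), sort_keys=True)
        )
        meta = {
            "config_hash": model.config.config_hash(),
            "manifest_hash": manifest_hash,
            "log": [float(x) for x in (log or [])],
        }
        z.writestr("meta.yaml", yaml.safe_dump(meta))


def load_checkpoint(path):
    """Rebuild a model from :func:`save_checkpoint` output."""
    with zipfile.ZipFile(path) as z:
        config = ModelConfig(**yaml.safe_load(z.read("config.yaml")))
        meta = yaml.safe_load(z.read("meta.yaml"))
        weights = np.load(io.BytesIO(z.read("weights.npz")))
    model = (
        SDFAutoencoder(config)
        if config.decoder == "implicit_sdf"
        else PointCloudAutoencoder(config)
    )
    for i, p in enumerate(model.params):
        p.data = weights[f"p{i}"]
    return model, meta
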