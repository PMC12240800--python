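"""Decoders: template-folding point-cloud generator and implicit SDF head.

The folding decoder concatenates the conditioning representation with
source points from a fixed template (a 2D plane grid, or a sphere for the
synthetic packing data) and applies two folding MLPs with ReLU activations
interleaved. The output is a canonical, orientation-normalized
reconstruction; the caller restores orientation by multiplying the XYZ
part with the rotation matrix recovered from the equivariant latent.

The implicit SDF decoder maps (conditioning ++ query coordinate) to one
scalar signed distance per query and is trained with squared error against
clipped SDF targets.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor

__all__ = ["FoldingDecoder", "ImplicitSDFDecoder", "make_template"]


def make_template(kind: str, m: int) -> np.ndarray:
    """Template source points: 'plane' grid on [-0.5, 0.5]^2 or a 'sphere'
    (Fibonacci lattice, radius 0.5)."""
    if kind == "plane":
        side = int(np.ceil(np.sqrt(m)))
        g = np.linspace(-0.5, 0.5, side)
        xx, yy = np.meshgrid(g, g)
        pts = np.column_stack([xx.ravel(), yy.ravel()])[:m]
        return pts
    if kind == "sphere":
        i = np.arange(m) + 0.5
        phi = np.arccos(1 - 2 * i / m)
        golden = np.pi * (1 + np.sqrt(5.0))
        theta = golden * i
        return 0.5 * np.column_stack(
            [
                np.cos(theta) * np.sin(phi),
                np.sin(theta) * np.sin(phi),
                np.cos(phi),
            ]
        )
    raise ValueError("template kind must be 'plane' or 'sphere'")


class _MLP:
    """Plain scalar MLP with ReLU between layers."""

    def __init__(self, dims, rng, final_zero=False):
        self.layers = []
        for i, (din, dout) in enumerate(zip(dims[:-1], dims[1:])):
            scale = np.sqrt(2.0 / din)
            w = rng.normal(scale=scale, size=(dout, din))
            if final_zero and i == len(dims) - 2:
                w = np.zeros((dout, din))
            self.layers.append((Parameter(w), Parameter(np.zeros(dout))))

    def __call__(self, x: Tensor) -> Tensor:
        for i, (w, b) in enumerate(self.layers):
            x = ad.add(ad.einsum("oi,mi->mo", w, x), b)
            if i < len(self.layers) - 1:
                x = ad.relu(x)
        return x

    @property
    def params(self):
        return [p for wb in self.layers for p in wb]


class FoldingDecoder:
    """Two-stage folding of a fixed template conditioned on a representation.

    Parameters
    ----------
    rep_dim:
        Length of the conditioning vector (the invariant representation).
    template:
        'plane' or 'sphere'.
    m:
        Number of template (= output) points.
    out_dim:
        3 for XYZ clouds, 4 when an intensity coordinate is emitted.
    """

    def __init__(
        self,
        rep_dim: int,
        template: str = "plane",
        m: int = 256,
        out_dim: int = 3,
        hidden: int = 64,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.template_kind = template
        self.template = make_template(template, m)
        self.m = m
        self.out_dim = out_dim
        tdim = self.template.shape[1]
        self.fold1 = _MLP([rep_dim + tdim, hidden, hidden, 3], rng)
        self.fold2 = _MLP([rep_dim + 3, hidden, hidden, out_dim], rng)

    @property
    def params(self):
        return self.fold1.params + self.fold2.params

    def __call__(self, rep, rotation=None) -> Tensor:
        """Decode a representation into an (m, out_dim) cloud.

        ``rep`` is a length-``rep_dim`` Tensor or array. If ``rotation`` (a
        3x3 Tensor/array, rows orthonormal) is given, the canonical XYZ
        coordinates are reoriented by right-multiplication with it.
        """
        rep = ad.as_tensor(rep)
        rep_rows = ad.tile_rows(rep, self.m)
        t = Tensor(self.template)
        h = self.fold1(ad.concat([rep_rows, t], axis=1))
        y = self.fold2(ad.concat([rep_rows, h], axis=1))
        if rotation is None:
            return y
        rotation = ad.as_tensor(rotation)
        if self.out_dim == 3:
            return ad.einsum("mi,ij->mj", y, rotation)
        xyz = ad.einsum(
            "mi,ij->mj", _slice_cols(y, 0, 3), rotation
        )
        return ad.concat([xyz, _slice_cols(y, 3, 4)], axis=1)


def _slice_cols(x: Tensor, lo: int, hi: int) -> Tensor:
    idx = np.arange(x.shape[1])

    def grad_fn(g):
        out = np.zeros(x.shape)
        out[:, lo:hi] = g
        return (out,)

    return Tensor(x.data[:, lo:hi], (x,), grad_fn)


class ImplicitSDFDecoder:
    """MLP from (conditioning ++ query XYZ) to a scalar signed distance."""

    def __init__(
        self,
        cond_dim: int,
        hidden: int = 64,
        n_hidden_layers: int = 4,
        grid_size: float = 32.0,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        dims = [cond_dim + 3] + [hidden] * n_hidden_layers + [1]
        self.mlp = _MLP(dims, rng)
        self.cond_dim = cond_dim
        # queries live in [0, grid_size]^3; map to ~[-1, 1] for the MLP
        self.query_center = grid_size / 2.0
        self.query_scale = grid_size / 2.0

    @property
    def params(self):
        return self.mlp.params

    def __call__(self, cond, queries: np.ndarray) -> Tensor:
        """Predict SDF values at (Q, 3) query points; returns shape (Q,)."""
        queries = np.asarray(queries, dtype=np.float64)
        queries = (queries - self.query_center) / self.query_scale
        cond = ad.as_tensor(cond)
        rows = ad.tile_rows(cond, len(queries))
        x = ad.concat([rows, Tensor(queries)], axis=1)
        out = self.mlp(x)
        return ad.reshape(out, (len(queries),))
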