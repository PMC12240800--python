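"""Rotation-equivariant vector-neuron (VN) layers and the DGCNN encoder.

Every feature is a stack of 3D vectors, shape (..., C, 3). VN linear maps
mix channels only (never the three spatial components), so a rotation R of
the input commutes with every layer: f(x R^T) = f(x) R^T per channel. The
VN leaky ReLU rescales each vector channel based on its projection onto a
learned direction, leaking by a slope alpha when the projection is
negative, which preserves equivariance because the learned direction is
itself an equivariant linear map of the features.

The encoder is a dynamic-graph edge-convolution stack: k-nearest-neighbor
graphs are recomputed per block from the current (flattened) features,
per-edge messages combine neighbor features, feature differences, the
cross product of neighbor features with the anchor point, and the anchor
point itself; messages pass through a VN linear + VN leaky ReLU and are
mean-pooled over neighbors. Intermediate block outputs are concatenated
and mixed into the final C x 3 latent, mean-pooled over points. The
rotation-invariant representation is the per-channel norm of that latent;
the rotation matrix is recovered by Gram-Schmidt on two designated latent
channels.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor

__all__ = [
    "VNLinear",
    "VNLeakyReLU",
    "VNEdgeConv",
    "VNEncoder",
    "knn_graph",
    "invariant_representation",
    "rotation_from_latent",
]


def knn_graph(points: np.ndarray, k: int = 20) -> np.ndarray:
    """Indices of the k nearest Euclidean neighbors, excluding self.

    ``points`` may be (N, D) flattened features. Ties are broken by lower
    index (stable argsort), so the graph of a rigidly rotated cloud is
    identical to the graph of the original.
    """
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    sq = np.einsum("nd,nd->n", points, points)
    d2 = sq[:, None] + sq[None, :] - 2.0 * points @ points.T
    np.fill_diagonal(d2, np.inf)
    # round distances so exact geometric ties survive float noise and are
    # resolved by index order
    order = np.argsort(np.round(d2, 12), axis=1, kind="stable")
    return order[:, :k]


def _vn_linear(weight: Tensor, x: Tensor) -> Tensor:
    """Channel-mixing linear map over the channel axis of (..., C, 3)."""
    if x.ndim == 3:
        return ad.einsum("oc,ncd->nod", weight, x)
    if x.ndim == 4:
        return ad.einsum("oc,nkcd->nkod", weight, x)
    raise ValueError(f"unsupported feature rank {x.ndim}")


class VNLinear:
    def __init__(self, in_channels: int, out_channels: int, rng):
        scale = 1.0 / np.sqrt(in_channels)
        self.weight = Parameter(
            rng.uniform(-scale, scale, size=(out_channels, in_channels))
        )

    def __call__(self, x: Tensor) -> Tensor:
        return _vn_linear(self.weight, x)

    @property
    def params(self):
        return [self.weight]


class VNLeakyReLU:
    """Direction-aware nonlinearity; fixes 0 and preserves equivariance."""

    def __init__(self, channels: int, rng, alpha: float = 0.2):
        scale = 1.0 / np.sqrt(channels)
        self.direction = Parameter(
            rng.uniform(-scale, scale, size=(channels, channels))
        )
        self.alpha = alpha

    def __call__(self, x: Tensor) -> Tensor:
        d = _vn_linear(self.direction, x)
        dot = ad.reduce_sum(ad.mul(x, d), axis=-1, keepdims=True)
        dnorm2 = ad.add(
            ad.reduce_sum(ad.square(d), axis=-1, keepdims=True), 1e-12
        )
        neg = (dot.data < 0).astype(np.float64)  # constant branch mask
        correction = ad.mul(ad.mul(neg, ad.div(dot, dnorm2)), d)
        return ad.sub(x, ad.mul(1.0 - self.alpha, correction))

    @property
    def params(self):
        return [self.direction]


class VNEdgeConv:
    """One VN edge-convolution block (message -> VN linear -> VN leaky ReLU,
    mean-pooled over neighbors)."""

    def __init__(self, in_channels: int, out_channels: int, rng, alpha=0.2):
        # message channels: neighbor feats, feat differences, cross products
        # with the anchor point, and the anchor point itself
        self.msg_channels = 3 * in_channels + 1
        self.linear = VNLinear(self.msg_channels, out_channels, rng)
        self.act = VNLeakyReLU(out_channels, rng, alpha)

    def __call__(self, features: Tensor, points: np.ndarray, graph) -> Tensor:
        n, k = graph.shape
        f_j = ad.gather(features, graph)  # (N, k, C, 3)
        f_i = _expand_anchor(features)
        diff = ad.sub(f_j, f_i)
        p_i = points[:, None, None, :]  # (N, 1, 1, 3), constant
        crossed = ad.cross(f_j, Tensor(np.broadcast_to(p_i, f_j.shape).copy()))
        p_chan = Tensor(
            np.broadcast_to(p_i, (n, k, 1, 3)).copy()
        )  # anchor point as a 1-channel vector feature
        msg = ad.concat([f_j, diff, crossed, p_chan], axis=2)
        out = self.act(self.linear(msg))
        return ad.reduce_mean(out, axis=1)

    @property
    def params(self):
        return self.linear.params + self.act.params


def _expand_anchor(features: Tensor) -> Tensor:
    """Insert a neighbor axis: (N, C, 3) -> (N, 1, C, 3), differentiable."""
    data = features.data[:, None, :, :]

    def grad_fn(g):
        return (g.sum(axis=1),)

    return Tensor(data, (features,), grad_fn)


class VNEncoder:
    """VN-DGCNN encoder producing a C x 3 equivariant latent.

    Parameters
    ----------
    bottleneck:
        Number of latent vector channels C; the invariant representation
        has dimension C.
    hidden_channels:
        Output channels of each edge-conv block (default six blocks).
    k:
        Neighbors per point in the dynamic graphs.
    intensity_scale_channel:
        For 4D inputs, the intensity coordinate is carried as an extra
        input channel sharing the point's vector orientation: the channel
        is the XYZ direction scaled by the intensity value, which keeps
        the lift exactly equivariant.
    """

    def __init__(
        self,
        bottleneck: int = 64,
        hidden_channels=(16, 16, 16, 32, 32, 32),
        k: int = 20,
        alpha: float = 0.2,
        input_dim: int = 3,
        pool: str = "max",
        seed: int = 0,
    ):
        if input_dim not in (3, 4):
            raise ValueError("input_dim must be 3 or 4")
        if pool not in ("mean", "max"):
            raise ValueError("pool must be 'mean' or 'max'")
        rng = np.random.default_rng(seed)
        self.k = k
        self.bottleneck = bottleneck
        self.input_dim = input_dim
        self.pool = pool
        in_ch = 1 if input_dim == 3 else 2
        self.blocks = []
        for out_ch in hidden_channels:
            self.blocks.append(VNEdgeConv(in_ch, out_ch, rng, alpha))
            in_ch = out_ch
        self.final = VNLinear(int(np.sum(hidden_channels)), bottleneck, rng)

    @property
    def params(self):
        out = []
        for b in self.blocks:
            out.extend(b.params)
        out.extend(self.final.params)
        return out

    def lift(self, pointcloud: np.ndarray) -> Tensor:
        """Initial vector features from an (N, 3) or (N, 4) cloud."""
        pointcloud = np.asarray(pointcloud, dtype=np.float64)
        xyz = pointcloud[:, :3]
        if self.input_dim == 3:
            feats = xyz[:, None, :]
        else:
            if pointcloud.shape[1] != 4:
                raise ValueError("encoder configured for 4D input")
            w = pointcloud[:, 3:4]
            feats = np.stack([xyz, xyz * w], axis=1)
        return Tensor(feats)

    def __call__(self, pointcloud: np.ndarray) -> Tensor:
        """Encode a point cloud into the (C, 3) equivariant latent."""
        pointcloud = np.asarray(pointcloud, dtype=np.float64)
        n = len(pointcloud)
        if n <= self.k:
            raise ValueError("point count must exceed k")
        xyz = pointcloud[:, :3]
        feats = self.lift(pointcloud)
        intermediates = []
        for i, block in enumerate(self.blocks):
            graph_feats = xyz if i == 0 else feats.data.reshape(n, -1)
            graph = knn_graph(graph_feats, self.k)
            feats = block(feats, xyz, graph)
            if not np.all(np.isfinite(feats.data)):
                raise FloatingPointError(
                    f"non-finite activations in encoder block {i}"
                )
            intermediates.append(feats)
        collated = ad.concat(intermediates, axis=1)
        latent = self.final(collated)  # (N, C, 3)
        if self.pool == "mean":
            return ad.reduce_mean(latent, axis=0)  # (C, 3)
        return _vn_max_pool(latent)


def _vn_max_pool(latent: Tensor) -> Tensor:
    """Equivariant max pooling over points.

    Per channel, selects the point whose feature has the largest projection
    onto the channel's mean direction; the projections are
    rotation-invariant, so the selection (and hence equivariance) is
    preserved under rotation of the input.
    """
    d = latent.data.mean(axis=0)  # (C, 3)
    proj = np.einsum("ncd,cd->nc", latent.data, d)
    idx = proj.argmax(axis=0)  # (C,)
    c = latent.shape[1]

    def grad_fn(g):
        out = np.zeros(latent.shape)
        out[idx, np.arange(c), :] = g
        return (out,)

    return Tensor(latent.data[idx, np.arange(c), :], (latent,), grad_fn)


def invariant_representation(latent) -> np.ndarray:
    """Per-channel Euclidean norms of a (C, 3) latent (numpy output)."""
    data = latent.data if isinstance(latent, Tensor) else np.asarray(latent)
    return np.linalg.norm(data, axis=-1)


def invariant_representation_t(latent: Tensor) -> Tensor:
    """Differentiable per-channel norms of a (C, 3) latent."""
    return ad.sqrt(
        ad.add(ad.reduce_sum(ad.square(latent), axis=-1), 1e-12)
    )


def rotation_from_latent(latent, channels=(0, 1)):
    """Proper rotation matrix from two designated latent channels.

    Gram-Schmidt on the two channel vectors gives the first two rows; the
    cross product completes a right-handed orthonormal frame. Differentiable
    when given a Tensor; returns a Tensor in that case, else an ndarray.
    """
    is_tensor = isinstance(latent, Tensor)
    data = latent.data if is_tensor else np.asarray(latent, dtype=float)
    v1, v2 = data[channels[0]], data[channels[1]]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 <= 1e-8 or n2 <= 1e-8:
        bad = channels[0] if n1 <= 1e-8 else channels[1]
        raise ValueError(f"rotation channel {bad} is degenerate (near-zero)")
    cosang = abs(v1 @ v2) / (n1 * n2)
    if 1.0 - cosang < 1e-6:
        raise ValueError(
            f"rotation channels {channels} are parallel within tolerance"
        )
    if not is_tensor:
        e1 = v1 / n1
        u2 = v2 - (v2 @ e1) * e1
        e2 = u2 / np.linalg.norm(u2)
        return np.stack([e1, e2, np.cross(e1, e2)])
    rows = ad.gather(latent, np.array(channels))  # (2, 3)
    v1t = ad.gather(rows, np.array([0]))
    v2t = ad.gather(rows, np.array([1]))
    e1 = _normalize_row(v1t)
    dot = ad.reduce_sum(ad.mul(v2t, e1), axis=-1, keepdims=True)
    u2 = ad.sub(v2t, ad.mul(dot, e1))
    e2 = _normalize_row(u2)
    e3 = ad.cross(e1, e2)
    return ad.concat([e1, e2, e3], axis=0)


def _normalize_row(v: Tensor) -> Tensor:
    norm = ad.sqrt(
        ad.add(ad.reduce_sum(ad.square(v), axis=-1, keepdims=True), 1e-30)
    )
    return ad.div(v, norm)
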