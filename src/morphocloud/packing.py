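"""Synthetic packing simulator for punctate-structure point clouds.

Generates nucleus-like closed meshes (randomly deformed ellipsoids) and
packs point clouds inside them under six spatial rules — random, radial,
surface, and planar gradients with the plane normal at 0, 45 or 90 degrees
to the z axis. The planar normals follow the convention that the nucleus's
longest axis is y: theta=0 -> (0,0,1), theta=45 -> (0, 1/sqrt2, 1/sqrt2),
theta=90 -> (0,1,0).

Gradient rules use exponential weights exp(+/- beta * distance): monotone in
the stated bias direction and reducing to the uniform rule at beta = 0.
Points are drawn by rejection sampling so the target density is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import meshquery

__all__ = [
    "NucleusShape",
    "PackingRule",
    "PackedPointCloud",
    "PLANAR_NORMALS",
    "DEFAULT_RULES",
    "make_nucleus_shape",
    "rule_weight",
    "pack_points",
    "generate_packing_dataset",
]

PLANAR_NORMALS = {
    0: np.array([0.0, 0.0, 1.0]),
    45: np.array([0.0, 1.0, 1.0]) / np.sqrt(2.0),
    90: np.array([0.0, 1.0, 0.0]),
}

#: default gradient sharpness per rule kind, chosen so the six rules are
#: visually and statistically separable while rejection sampling stays
#: tractable. Radial and surface betas are in inverse length units of the
#: mesh coordinates (nuclei span roughly -10..10). The planar beta applies
#: to the plane distance normalized by the shape's extent along the rule
#: normal, so all three plane orientations get equally sharp gradients in
#: anisotropic nuclei (on the unit sphere the normalization is 1 and the
#: weight reduces to exp(beta * |d|)).
DEFAULT_BETA = {"random": 0.0, "radial": 0.5, "surface": 1.5, "planar": 4.0}


@dataclass(frozen=True)
class PackingRule:
    """Spatial packing rule.

    ``kind`` is one of random / radial / surface / planar; ``plane_normal``
    is only meaningful for planar rules; ``strength`` is the non-negative
    gradient sharpness beta (ignored for random).
    """

    kind: str
    plane_normal: np.ndarray | None = None
    strength: float = 0.0
    theta_deg: float | None = None

    def __post_init__(self):
        if self.kind not in {"random", "radial", "surface", "planar"}:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.strength < 0:
            raise ValueError("strength must be non-negative")
        if self.kind == "planar":
            if self.plane_normal is None:
                raise ValueError("planar rule requires plane_normal")
            n = np.asarray(self.plane_normal, dtype=float)
            if abs(np.linalg.norm(n) - 1.0) > 1e-9:
                raise ValueError("plane_normal must have unit norm")
            object.__setattr__(self, "plane_normal", n)

    @property
    def label(self) -> str:
        if self.kind == "planar" and self.theta_deg is not None:
            return f"planar{int(self.theta_deg)}"
        return self.kind


def planar_rule(theta_deg: int, strength: float | None = None) -> PackingRule:
    """Planar rule at one of the three canonical orientations."""
    if theta_deg not in PLANAR_NORMALS:
        raise ValueError(f"theta must be one of {sorted(PLANAR_NORMALS)}")
    beta = DEFAULT_BETA["planar"] if strength is None else strength
    return PackingRule("planar", PLANAR_NORMALS[theta_deg], beta, theta_deg)


def default_rules(beta: dict | None = None) -> list[PackingRule]:
    """The six canonical rules with default (or overridden) sharpness."""
    b = dict(DEFAULT_BETA)
    if beta:
        b.update(beta)
    return [
        PackingRule("random"),
        PackingRule("radial", strength=b["radial"]),
        PackingRule("surface", strength=b["surface"]),
        planar_rule(0, b["planar"]),
        planar_rule(45, b["planar"]),
        planar_rule(90, b["planar"]),
    ]


DEFAULT_RULES = default_rules()


@dataclass
class NucleusShape:
    """Closed triangulated nucleus mesh."""

    vertices: np.ndarray
    faces: np.ndarray
    centroid: np.ndarray
    seed: int
    _mesh: trimesh.Trimesh = field(repr=False, default=None)

    @property
    def mesh(self) -> trimesh.Trimesh:
        if self._mesh is None:
            self._mesh = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._mesh

    @property
    def volume(self) -> float:
        return float(self.mesh.volume)


@dataclass
class PackedPointCloud:
    points: np.ndarray
    rule: PackingRule
    shape_id: str
    seed: int


def make_nucleus_shape(
    axes=(1.0, 1.0, 1.0),
    deform_amplitude: float = 0.0,
    resolution: int = 4,
    seed: int = 0,
) -> NucleusShape:
    """Create a watertight, radially perturbed ellipsoid mesh.

    The perturbation is a smooth low-order random field: a sum of real
    spherical harmonics up to degree 3 with seeded Gaussian coefficients,
    rescaled to relative amplitude ``deform_amplitude`` and applied to the
    radius before anisotropic scaling by ``axes``.
    """
    axes = np.asarray(axes, dtype=float)
    if np.any(axes <= 0):
        raise ValueError("axes must be positive")
    if not (0 <= deform_amplitude < 1):
        raise ValueError("deform_amplitude must be in [0, 1)")
    if resolution < 2:
        raise ValueError("resolution must be >= 2 icosphere subdivisions")
    base = trimesh.creation.icosphere(subdivisions=resolution, radius=1.0)
    verts = np.asarray(base.vertices, dtype=np.float64)
    if deform_amplitude > 0:
        rng = np.random.default_rng(seed)
        f = _random_smooth_field(verts, rng, max_degree=3)
        f = f / max(np.abs(f).max(), 1e-12)
        verts = verts * (1.0 + deform_amplitude * f)[:, None]
    verts = verts * axes[None, :]
    mesh = trimesh.Trimesh(vertices=verts, faces=base.faces, process=False)
    if not mesh.is_watertight:
        raise RuntimeError(
            "nucleus mesh is not watertight "
            f"(axes={tuple(axes)}, amplitude={deform_amplitude}, seed={seed})"
        )
    if mesh.volume <= 0:
        raise RuntimeError("nucleus mesh has non-positive volume")
    return NucleusShape(
        vertices=np.asarray(mesh.vertices),
        faces=np.asarray(mesh.faces),
        centroid=np.asarray(mesh.center_mass),
        seed=seed,
        _mesh=mesh,
    )


def _random_smooth_field(unit_verts, rng, max_degree=3):
    """Random band-limited scalar field on the unit sphere.

    Uses low-order polynomial harmonics of the direction vector (constant,
    linear, quadratic and cubic monomials), which span the same smooth
    low-frequency space as spherical harmonics up to the given degree.
    """
    x, y, z = unit_verts.T
    basis = [np.ones_like(x), x, y, z]
    if max_degree >= 2:
        basis += [x * y, y * z, x * z, x * x - y * y, 3 * z * z - 1]
    if max_degree >= 3:
        basis += [x * y * z, z * (x * x - y * y), x * (5 * z * z - 1)]
    coef = rng.normal(size=len(basis))
    return np.sum([c * b for c, b in zip(coef, basis)], axis=0)


def _plane_distance(points, centroid, normal):
    return (points - centroid[None, :]) @ normal


def rule_weight(points, shape: NucleusShape, rule: PackingRule) -> np.ndarray:
    """Unnormalized sampling weight of each point under ``rule``.

    Only defined for points inside the mesh; raises otherwise.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    inside = meshquery.contains(shape.mesh, points)
    if not np.all(inside):
        raise ValueError("rule_weight requested for a point outside the mesh")
    return _rule_weight_unchecked(points, shape, rule)


def _rule_weight_unchecked(points, shape, rule):
    beta = rule.strength
    if rule.kind == "random" or beta == 0:
        return np.ones(len(points))
    if rule.kind == "planar":
        d = np.abs(_plane_distance(points, shape.centroid, rule.plane_normal))
        return np.exp(beta * d / _plane_extent(shape, rule.plane_normal))
    if rule.kind == "radial":
        r = np.linalg.norm(points - shape.centroid[None, :], axis=1)
        return np.exp(-beta * r)
    if rule.kind == "surface":
        dist = meshquery.surface_distance(shape.mesh, points)
        return np.exp(-beta * dist)
    raise ValueError(rule.kind)


def _plane_extent(shape, normal):
    """Max |distance| of mesh vertices to the centroid plane with ``normal``."""
    d = np.abs(_plane_distance(shape.vertices, shape.centroid, normal))
    return max(float(d.max()), 1e-12)


def _weight_upper_bound(shape, rule):
    """Finite upper bound of the rule weight over the mesh interior."""
    if rule.kind == "planar":
        # normalized plane distance is at most 1 inside the mesh
        return float(np.exp(rule.strength))
    # radial and surface weights peak at 1; random is 1
    return 1.0


def pack_points(
    shape: NucleusShape,
    rule: PackingRule,
    n: int = 256,
    seed: int = 0,
    min_acceptance: float = 1e-4,
) -> PackedPointCloud:
    """Pack ``n`` points inside the mesh by rejection sampling.

    Proposals are uniform in the bounding box; accepted first by mesh
    containment and then with probability weight / weight_bound, which makes
    the interior density exactly proportional to the rule weight.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = shape.mesh.bounds
    bound = _weight_upper_bound(shape, rule)
    out = []
    proposed = accepted = 0
    # batch bounded above so proposal buffers stay modest in memory
    batch = min(max(4 * n, 512), 16384)
    while sum(len(o) for o in out) < n:
        cand = rng.uniform(lo, hi, size=(batch, 3))
        proposed += batch
        cand = cand[meshquery.contains(shape.mesh, cand)]
        if len(cand):
            w = _rule_weight_unchecked(cand, shape, rule)
            keep = rng.uniform(0, bound, size=len(cand)) < w
            cand = cand[keep]
            accepted += len(cand)
            if len(cand):
                out.append(cand)
        if proposed > 10 * batch and accepted / proposed < min_acceptance:
            raise RuntimeError(
                f"rejection acceptance rate {accepted / proposed:.2e} below "
                f"{min_acceptance:.0e}; lower beta for rule {rule.label!r}"
            )
    points = np.concatenate(out, axis=0)[:n]
    return PackedPointCloud(points=points, rule=rule, shape_id="", seed=seed)


@dataclass
class PackingConfig:
    """Nucleus-shape sampling ranges for the packing dataset.

    Semi-axes are in the voxel-like length units of the point clouds
    (typical coordinate range -10..10). The y axis is the longest, matching
    nuclei pre-aligned to their longest axis, and anisotropy is broad enough
    to include high-aspect-ratio shapes for which planar 0 and 45 differ.
    """

    n_points: int = 256
    axes_x: tuple = (5.0, 8.0)
    axes_y: tuple = (8.0, 14.0)
    axes_z: tuple = (3.5, 6.0)
    deform_amplitude: float = 0.15
    resolution: int = 2


def sample_nucleus(config: PackingConfig, seed: int) -> NucleusShape:
    """Draw one nucleus shape with randomized semi-axes."""
    rng = np.random.default_rng(seed)
    axes = np.array(
        [
            rng.uniform(*config.axes_x),
            rng.uniform(*config.axes_y),
            rng.uniform(*config.axes_z),
        ]
    )
    return make_nucleus_shape(
        axes=axes,
        deform_amplitude=config.deform_amplitude,
        resolution=config.resolution,
        seed=int(rng.integers(2**31 - 1)),
    )


def generate_packing_dataset(
    out_dir,
    n_shapes_per_rule: int = 254,
    rules: list[PackingRule] | None = None,
    config: PackingConfig | None = None,
    seed: int = 0,
    overwrite: bool = False,
    write_meshes: bool = True,
):
    """Generate the packing dataset and write a manifest.

    The same ``n_shapes_per_rule`` nuclei are shared across rules, so the
    output has ``n_shapes_per_rule * len(rules)`` point clouds. Returns the
    manifest DataFrame (also written as ``manifest.csv``).
    """
    if n_shapes_per_rule < 1:
        raise ValueError("n_shapes_per_rule must be >= 1")
    rules = list(rules) if rules is not None else default_rules()
    config = config or PackingConfig()
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} exists; pass overwrite=True to replace it"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    shape_seeds, pack_seeds = ss.spawn(2)
    shape_children = shape_seeds.spawn(n_shapes_per_rule)
    pack_children = pack_seeds.spawn(n_shapes_per_rule * len(rules))
    rows = []
    for i in range(n_shapes_per_rule):
        shape_seed = int(shape_children[i].generate_state(1)[0] % (2**31 - 1))
        shape = sample_nucleus(config, shape_seed)
        mesh_path = out_dir / f"nucleus_{i:04d}.ply"
        if write_meshes:
            shape.mesh.export(mesh_path)
        for j, rule in enumerate(rules):
            pack_seed = int(
                pack_children[i * len(rules) + j].generate_state(1)[0]
                % (2**31 - 1)
            )
            cloud = pack_points(shape, rule, n=config.n_points, seed=pack_seed)
            cloud.shape_id = f"nucleus_{i:04d}"
            cloud_id = f"{cloud.shape_id}_{rule.label}"
            npz_path = out_dir / f"{cloud_id}.npz"
            np.savez(npz_path, points=cloud.points)
            rows.append(
                {
                    "id": cloud_id,
                    "rule": rule.label,
                    "theta_deg": rule.theta_deg,
                    "seed": pack_seed,
                    "n_points": len(cloud.points),
                    "mesh_path": mesh_path.name if write_meshes else "",
                    "cloud_path": npz_path.name,
                    "shape_seed": shape_seed,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    return manifest
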