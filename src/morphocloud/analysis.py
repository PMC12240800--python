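"""Latent-space interpretation and perturbation profiling.

Tools for making learned representations biologically interpretable:

* PCA latent walks — step along a principal component in units of its
  standard deviation and decode (or retrieve the nearest real example to)
  each map point;
* archetypal analysis (principal convex hull) — approximate every
  observation as a convex combination of a few extreme archetypes;
* nuclear-volume pseudo-time bins — equal-count quantile bins of nuclear
  volume with per-bin mean representations and nearest real examples;
* two-class LDA axes of phenotypic difference with examples retrieved
  along the axis;
* perturbation detection: per-treatment mean average precision (mAP)
  against control with permutation p-values and Benjamini-Hochberg
  q-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pca_latent_walk",
    "fit_archetypes",
    "ArchetypeSet",
    "volume_bin_profiles",
    "lda_axis",
    "mean_average_precision",
    "perturbation_map_qvalue",
    "PerturbationResult",
]


def pca_latent_walk(
    representations,
    component: int = 0,
    map_points=(-2, -1, 0, 1, 2),
    decoder=None,
):
    """Walk along one principal component of a group of representations.

    Returns a dict with the walked representations at
    ``mean + sigma * map_point * loading`` and, if ``decoder`` is given,
    the decoded reconstructions; the nearest real sample index per map
    point is always included.
    """
    x = np.asarray(representations, dtype=float)
    if len(x) < 3:
        raise ValueError("group must have at least 3 members")
    pca = PCA(n_components=min(len(x) - 1, x.shape[1]))
    pca.fit(x)
    if component >= pca.n_components_:
        raise ValueError(
            f"component {component} beyond available rank {pca.n_components_}"
        )
    loading = pca.components_[component]
    sigma = np.sqrt(pca.explained_variance_[component])
    walked = np.stack(
        [x.mean(axis=0) + sigma * t * loading for t in map_points]
    )
    d = np.linalg.norm(x[None, :, :] - walked[:, None, :], axis=2)
    nearest = d.argmin(axis=1)
    out = {
        "map_points": np.asarray(map_points, dtype=float),
        "representations": walked,
        "nearest_index": nearest,
        "explained_variance_ratio": float(
            pca.explained_variance_ratio_[component]
        ),
    }
    if decoder is not None:
        out["decoded"] = [decoder(w) for w in walked]
    return out


@dataclass
class ArchetypeSet:
    """Result of archetypal analysis: X ~ W @ (B @ X)."""

    archetypes: np.ndarray  # (A, C)
    weights: np.ndarray  # (n, A), rows on the simplex
    mixing: np.ndarray  # (A, n), rows on the simplex (B matrix)
    residual_norm: float
    converged: bool


def _simplex_nnls(A, b, penalty=200.0):
    """Least squares min ||A x - b|| subject to x >= 0, sum x = 1.

    Solved as NNLS on the system augmented with a heavily weighted
    sum-to-one row (standard penalty trick).
    """
    n = A.shape[1]
    A_aug = np.vstack([A, penalty * np.ones((1, n))])
    b_aug = np.append(b, penalty)
    x, _ = nnls(A_aug, b_aug)
    s = x.sum()
    return x / s if s > 0 else np.full(n, 1.0 / n)


def fit_archetypes(
    representations,
    n_archetypes: int,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    n_restarts: int = 5,
) -> ArchetypeSet:
    """Archetypal analysis by alternating simplex-constrained least squares.

    Minimizes ||X - W (B X)||^2 with rows of W (weights) and B (mixing)
    on the simplex, so archetypes Z = B X live in the convex hull of the
    data. Multiple seeded restarts; the best residual is kept.
    """
    x = np.asarray(representations, dtype=float)
    n = len(x)
    if n_archetypes > n:
        raise ValueError("more archetypes than samples")
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        result = _fit_archetypes_once(x, n_archetypes, max_iter, tol, rng)
        if best is None or result.residual_norm < best.residual_norm:
            best = result
    return best


def _fit_archetypes_once(x, a, max_iter, tol, rng):
    n, c = x.shape
    # initialize archetypes from random data points
    z = x[rng.choice(n, size=a, replace=False)].copy()
    prev = np.inf
    converged = False
    w = np.full((n, a), 1.0 / a)
    b = np.full((a, n), 1.0 / n)
    for _ in range(max_iter):
        for i in range(n):
            w[i] = _simplex_nnls(z.T, x[i])
        # update archetypes: solve W z = x in least squares, then express
        # each archetype as a simplex combination of data rows
        zt, *_ = np.linalg.lstsq(w, x, rcond=None)
        for j in range(a):
            b[j] = _simplex_nnls(x.T, zt[j])
        z = b @ x
        resid = np.linalg.norm(x - w @ z)
        if abs(prev - resid) < tol * max(prev, 1.0):
            converged = True
            prev = resid
            break
        prev = resid
    if not converged:
        import warnings

        warnings.warn(
            f"archetypal analysis did not converge in {max_iter} iterations",
            stacklevel=3,
        )
    return ArchetypeSet(
        archetypes=z,
        weights=w,
        mixing=b,
        residual_norm=float(prev),
        converged=converged,
    )


def volume_bin_profiles(representations, volumes, n_bins: int = 5):
    """Equal-count quantile bins of nuclear volume with per-bin profiles.

    Returns a DataFrame with one row per bin: volume range, member count,
    mean representation (as a list column) and the index of the nearest
    real sample to the bin mean.
    """
    x = np.asarray(representations, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    if len(x) < n_bins:
        raise ValueError("fewer samples than bins")
    order = np.lexsort((np.arange(len(v)), v))  # stable: ties by sample id
    bins = np.array_split(order, n_bins)
    rows = []
    for i, members in enumerate(bins):
        mean_rep = x[members].mean(axis=0)
        nearest = members[
            np.linalg.norm(x[members] - mean_rep, axis=1).argmin()
        ]
        rows.append(
            {
                "bin": i,
                "n": len(members),
                "volume_lo": float(v[members].min()),
                "volume_hi": float(v[members].max()),
                "mean_representation": mean_rep,
                "nearest_index": int(nearest),
            }
        )
    return pd.DataFrame(rows)


def lda_axis(representations, binary_labels, n_examples: int = 5):
    """Two-class LDA direction with examples retrieved along the axis.

    Uses Ledoit-Wolf shrinkage of the within-class covariance (robust for
    small n relative to the latent dimension). Returns the unit axis, the
    per-sample projections, and ``n_examples`` sample indices at evenly
    spaced projection quantiles (monotone along the axis).
    """
    x = np.asarray(representations, dtype=float)
    y = np.asarray(binary_labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("binary_labels must contain exactly two classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError("both classes need >= 2 members")
    lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto")
    lda.fit(x, y)
    axis = lda.scalings_[:, 0]
    axis = axis / np.linalg.norm(axis)
    proj = x @ axis
    qs = np.linspace(0, 1, n_examples)
    targets = np.quantile(proj, qs)
    examples = [int(np.argmin(np.abs(proj - t))) for t in targets]
    return axis, proj, examples


def _average_precision(ranked_relevant: np.ndarray) -> float:
    """AP of a ranked boolean relevance list."""
    hits = np.flatnonzero(ranked_relevant)
    if len(hits) == 0:
        return 0.0
    precisions = (np.arange(len(hits)) + 1) / (hits + 1)
    return float(precisions.mean())


def mean_average_precision(treated, control) -> float:
    """mAP of retrieving same-treatment cells from the pooled set.

    For each treated cell, all other cells (treated and control) are
    ranked by Euclidean representation distance; relevant items are the
    other treated cells.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    pool = np.vstack([treated, control])
    labels = np.r_[np.ones(len(treated)), np.zeros(len(control))].astype(bool)
    aps = []
    for i in range(len(treated)):
        d = np.linalg.norm(pool - pool[i], axis=1)
        mask = np.ones(len(pool), dtype=bool)
        mask[i] = False
        order = np.argsort(d[mask], kind="stable")
        aps.append(_average_precision(labels[mask][order]))
    return float(np.mean(aps))


@dataclass
class PerturbationResult:
    drug: str
    map_score: float
    p_value: float
    q_value: float = np.nan
    n_treated: int = 0
    n_control: int = 0
    n_permutations: int = 0
    seed: int = 0

    @property
    def significant(self) -> bool:
        """q < 0.05, equivalently 1/q > 20."""
        return bool(self.q_value < 0.05)


def perturbation_map_qvalue(
    control_reps,
    treated_reps_by_drug: dict,
    n_permutations: int = 1000,
    seed: int = 0,
) -> list[PerturbationResult]:
    """Per-drug mAP with permutation p-values and BH q-values.

    The null permutes treatment labels within the pooled (treated +
    control) set; p = (1 + #{null mAP >= observed}) / (1 + n_permutations).
    q-values are Benjamini-Hochberg adjusted across drugs.
    """
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    control = np.asarray(control_reps, dtype=float)
    if len(control) < 2:
        raise ValueError("control group needs >= 2 members")
    results = []
    ss = np.random.SeedSequence(seed)
    for (drug, treated), child in zip(
        sorted(treated_reps_by_drug.items()), ss.spawn(len(treated_reps_by_drug))
    ):
        treated = np.asarray(treated, dtype=float)
        if len(treated) < 2:
            raise ValueError(f"treated group {drug!r} needs >= 2 members")
        observed = mean_average_precision(treated, control)
        rng = np.random.default_rng(child)
        pool = np.vstack([treated, control])
        n_t = len(treated)
        null = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = rng.permutation(len(pool))
            null[b] = mean_average_precision(
                pool[perm[:n_t]], pool[perm[n_t:]]
            )
        p = (1.0 + np.sum(null >= observed)) / (1.0 + n_permutations)
        results.append(
            PerturbationResult(
                drug=drug,
                map_score=observed,
                p_value=float(p),
                n_treated=n_t,
                n_control=len(control),
                n_permutations=n_permutations,
                seed=seed,
            )
        )
    qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results
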