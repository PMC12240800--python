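"""Multi-metric benchmark for learned representations.

Covers the three metric families used to compare models: generative
(reconstruction error, evolution energy / interpolate distance),
representation expressivity (compactness as Levina-Bickel intrinsic
dimension, classification and regression heads, rotation invariance
error), and efficiency (parameter count, inference time). A z-scored
summary table supports the polar-plot comparison across models, with signs
flipped so that larger is always better.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .nn.emd import emd

__all__ = [
    "reconstruction_error",
    "rotation_invariance_error",
    "compactness",
    "levina_bickel",
    "classification_score",
    "regression_score",
    "interpolation_metrics",
    "efficiency_report",
    "zscore_summary",
    "MetricReport",
]

#: metric orientation: True if larger values indicate a better model
HIGHER_IS_BETTER = {
    "reconstruction_error": False,
    "evolution_energy": False,
    "avg_interpolate_distance": False,
    "rotation_invariance_error": False,
    "compactness": False,
    "classification_accuracy": True,
    "regression_r2": True,
    "parameter_count": False,
    "inference_seconds_per_sample": False,
}


@dataclass
class MetricReport:
    """Tidy per-(model, metric) table with raw and z-scored values."""

    table: pd.DataFrame

    def to_json(self, path=None):
        text = self.table.to_json(orient="records")
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def reconstruction_error(model, samples) -> np.ndarray:
    """Per-sample reconstruction error.

    Punctate models: EMD between the input cloud and the reoriented
    reconstruction. Polymorphic (SDF) models: mean squared error between
    predicted and true clipped SDF values at the sample's query points.
    """
    out = []
    for s in samples:
        if hasattr(s, "sdf_values"):
            if not hasattr(model, "predict_sdf"):
                raise TypeError("SDF samples require an SDF model")
            pred = model.predict_sdf(s.surface_points, s.query_points)
            out.append(float(np.mean((pred.data - s.sdf_values) ** 2)))
        else:
            pts = np.asarray(s, dtype=float)
            recon = model.reconstruct(pts)
            out.append(emd(recon.data, pts))
    return np.asarray(out)


def rotation_invariance_error(
    embed_fn, samples, n_rotations: int = 5, seed: int = 0
) -> np.ndarray:
    """Spread of representations across random 3D rotations of each sample.

    For each sample: embed ``n_rotations`` uniformly rotated copies, return
    the mean pairwise Euclidean distance between the representations divided
    by the mean representation norm (scale-free across models).
    """
    if n_rotations < 2:
        raise ValueError("need at least 2 rotations")
    rng = np.random.default_rng(seed)
    out = []
    for s in samples:
        pts = np.asarray(s, dtype=float)
        reps = []
        for _ in range(n_rotations):
            R = Rotation.random(random_state=rng).as_matrix()
            rotated = pts.copy()
            rotated[:, :3] = rotated[:, :3] @ R.T
            reps.append(np.asarray(embed_fn(rotated), dtype=float))
        reps = np.stack(reps)
        norms = np.linalg.norm(reps, axis=1)
        if np.any(norms < 1e-300):
            raise ValueError("zero-norm representation")
        diffs = reps[:, None, :] - reps[None, :, :]
        iu = np.triu_indices(n_rotations, k=1)
        mean_dist = np.linalg.norm(diffs, axis=2)[iu].mean()
        out.append(mean_dist / norms.mean())
    return np.asarray(out)


def levina_bickel(x: np.ndarray, k: int) -> float:
    """Levina-Bickel maximum-likelihood intrinsic dimension at one k.

    m_k(x) = [ (1/(k-2)) * sum_{j=1}^{k-1} log(T_k(x) / T_j(x)) ]^{-1},
    averaged over points, with T_j the distance to the j-th neighbor. The
    (k-2) normalizer is the unbiased form of the maximum-likelihood
    estimator (the sum is Gamma(k-1, 1/m) distributed, so the inverse has
    expectation m/(k-2)).
    """
    x = np.asarray(x, dtype=float)
    if k < 3:
        raise ValueError("k must be >= 3")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    dist, _ = nn.kneighbors(x)
    t = dist[:, 1:]  # drop self
    if np.any(t[:, : k - 1] <= 0):
        warnings.warn(
            "duplicate points found; applying tiny distance perturbation",
            stacklevel=2,
        )
        t = np.maximum(t, 1e-12)
    logs = np.log(t[:, -1][:, None] / t[:, : k - 1])
    inv_m = logs.sum(axis=1) / (k - 2)
    return float(np.mean(1.0 / np.maximum(inv_m, 1e-300)))


def compactness(representations, k_min: int = 5, k_max: int = 20) -> float:
    """Intrinsic dimension averaged over k in [k_min, k_max] (lower =
    more compact)."""
    x = np.asarray(representations, dtype=float)
    if not (2 <= k_min <= k_max < len(x)):
        raise ValueError("need n > k_max >= k_min >= 2")
    return float(
        np.mean([levina_bickel(x, k) for k in range(k_min, k_max + 1)])
    )


def classification_score(
    representations,
    labels,
    top_k: int = 1,
    n_folds: int = 5,
    seed: int = 0,
):
    """Stratified k-fold top-k accuracy of multinomial logistic regression
    on standardized representations. Returns (mean, sd) over folds."""
    x = np.asarray(representations, dtype=float)
    y = np.asarray(labels)
    classes, y_enc = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    counts = np.bincount(y_enc)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members < {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(x, y_enc):
        clf = make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, random_state=seed),
        )
        clf.fit(x[tr], y_enc[tr])
        prob = clf.predict_proba(x[te])
        top = np.argsort(prob, axis=1)[:, -top_k:]
        accs.append(np.mean([y_enc[te][i] in top[i] for i in range(len(te))]))
    return float(np.mean(accs)), float(np.std(accs))


def regression_score(
    representations, targets, n_repeats: int = 5, n_folds: int = 5, seed: int = 0
):
    """Cross-validated ridge-regression R^2. Returns (mean, sd) over
    repeats."""
    x = np.asarray(representations, dtype=float)
    y = np.asarray(targets, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite")
    if np.std(y) == 0:
        raise ValueError("constant target")
    scores = []
    for rep in range(n_repeats):
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        preds = np.empty_like(y)
        for tr, te in kf.split(x):
            reg = make_pipeline(StandardScaler(), Ridge(alpha=1.0))
            reg.fit(x[tr], y[tr])
            preds[te] = reg.predict(x[te])
        ss_res = np.sum((y - preds) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        scores.append(1.0 - ss_res / ss_tot)
    return float(np.mean(scores)), float(np.std(scores))


def interpolation_metrics(
    model,
    pairs,
    all_representations,
    steps: int = 8,
    decode_distance=None,
):
    """Evolution energy and average interpolate distance per pair.

    For each pair of samples: linearly interpolate their representations in
    ``steps`` increments and decode each interpolant. Evolution energy is
    the summed reconstruction-space distance between consecutive
    interpolants; the default distance is the square root of the mean
    EMD matching cost (a length, so a linearly decoded path has energy
    independent of the step count). Callers may pass a custom
    ``decode_distance``. Average interpolate distance is the mean distance
    from each interpolated representation to its nearest neighbor among
    ``all_representations`` (an on-manifold proxy).
    """
    if steps < 2:
        raise ValueError("steps must be >= 2")
    all_reps = np.asarray(all_representations, dtype=float)
    nn = NearestNeighbors(n_neighbors=1).fit(all_reps)
    if decode_distance is None:
        def decode_distance(r1, r2):
            return np.sqrt(
                emd(model.decoder(r1).data, model.decoder(r2).data)
            )
    energies, avg_dists = [], []
    for rep_a, rep_b in pairs:
        rep_a = np.asarray(rep_a, dtype=float)
        rep_b = np.asarray(rep_b, dtype=float)
        ts = np.linspace(0.0, 1.0, steps)
        interps = [(1 - t) * rep_a + t * rep_b for t in ts]
        energy = sum(
            decode_distance(interps[i], interps[i + 1])
            for i in range(steps - 1)
        )
        d, _ = nn.kneighbors(np.stack(interps))
        energies.append(float(energy))
        avg_dists.append(float(d.mean()))
    return np.asarray(energies), np.asarray(avg_dists)


def efficiency_report(model, sample=None, n_timing: int = 3) -> dict:
    """Exact parameter count plus (hardware-dependent) timing estimate."""
    n_params = int(sum(p.data.size for p in model.params))
    seconds = None
    if sample is not None:
        tic = time.perf_counter()
        for _ in range(n_timing):
            model.representation(sample)
        seconds = (time.perf_counter() - tic) / n_timing
    report = {
        "parameter_count": n_params,
        "inference_seconds_per_sample": seconds,
        "estimated_energy": None,  # no device energy counters exposed here
    }
    return report


def zscore_summary(raw: pd.DataFrame) -> pd.DataFrame:
    """Z-score metric values across models, flipping lower-is-better signs.

    ``raw`` has columns (model, metric, value); the result adds a ``z``
    column with mean 0 per metric and sign such that larger is better.
    """
    out = raw.copy()
    zs = np.empty(len(out))
    for metric, group in out.groupby("metric"):
        if len(group) < 2:
            raise ValueError(f"need >= 2 models for metric {metric!r}")
        v = group["value"].to_numpy(dtype=float)
        sd = v.std()
        if sd == 0:
            warnings.warn(
                f"zero variance across models for {metric!r}; z set to 0",
                stacklevel=2,
            )
            z = np.zeros_like(v)
        else:
            z = (v - v.mean()) / sd
        if not HIGHER_IS_BETTER.get(metric, True):
            z = -z
        zs[group.index.to_numpy()] = z
    out["z"] = zs
    return out
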