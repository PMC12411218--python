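"""Global Field Power and cluster-based permutation contrasts.

GFP is the spatial standard deviation of the scalp potential across channels
at each time point — a reference-free index of evoked-response strength.
Condition contrasts on GFP time series are tested with a cluster-based
permutation procedure: sample-wise paired t-statistics, contiguous
supra-threshold runs scored by summed t (cluster mass), and a max-cluster
null built from sign flips of the participant-wise difference series.
Clustering here is over time only (the contrast series are one-dimensional).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "compute_gfp",
    "Cluster",
    "ClusterResult",
    "cluster_permutation_test",
    "nearfar_interaction",
]


def compute_gfp(epoch_mean: np.ndarray, *, demean: bool = True) -> np.ndarray:
    """GFP of a channels x samples evoked response.

    gfp(t) = sqrt( mean_k (v_k(t) - vbar(t))^2 ), i.e. the population spatial
    standard deviation after removing the spatial mean at each sample
    (average-reference convention; set ``demean=False`` to skip).
    """
    v = np.asarray(epoch_mean, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("epoch_mean must be a K x S matrix with K >= 2 channels")
    if demean:
        v = v - v.mean(axis=0, keepdims=True)
    return np.sqrt(np.mean(v**2, axis=0))


@dataclass(frozen=True)
class Cluster:
    start_idx: int
    end_idx: int  # inclusive
    start_ms: float
    end_ms: float
    mass: float
    p_corrected: float


@dataclass(frozen=True)
class ClusterResult:
    clusters: list[Cluster]
    threshold_t: float
    cluster_alpha: float
    corrected_alpha: float
    n_perm: int
    seed: int
    extra: dict = field(default_factory=dict)

    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corrected < self.corrected_alpha]

    def to_dict(self) -> dict:
        return {
            "clusters": [
                {
                    "start_ms": c.start_ms,
                    "end_ms": c.end_ms,
                    "mass": c.mass,
                    "p_corrected": c.p_corrected,
                }
                for c in self.clusters
            ],
            "threshold_t": self.threshold_t,
            "cluster_alpha": self.cluster_alpha,
            "corrected_alpha": self.corrected_alpha,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def _sample_t(diff: np.ndarray) -> np.ndarray:
    """Paired t per sample of an n_subjects x n_samples difference matrix."""
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd == 0, np.where(mean == 0, 0.0, np.inf * np.sign(mean)), t)


def _clusters_from_t(t: np.ndarray, threshold: float) -> list[tuple[int, int, float]]:
    """Contiguous runs of |t| > threshold with a common sign, scored by sum(t)."""
    above = np.abs(t) > threshold
    sign = np.sign(t)
    out: list[tuple[int, int, float]] = []
    i = 0
    s = t.size
    while i < s:
        if above[i]:
            j = i
            while j + 1 < s and above[j + 1] and sign[j + 1] == sign[i]:
                j += 1
            out.append((i, j, float(t[i : j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return out


def cluster_permutation_test(
    series_a: np.ndarray,
    series_b: np.ndarray,
    times_ms: np.ndarray,
    *,
    cluster_alpha: float = 0.05,
    corrected_alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Paired cluster-based permutation test of two GFP series sets.

    ``series_a``/``series_b`` are n_subjects x n_samples arrays with matching
    subject order.  The cluster-forming threshold is the two-sided t critical
    value at ``cluster_alpha``; the corrected p of each observed cluster is the
    (+1-smoothed) proportion of sign-flip permutation max-|mass| values at
    least as large as the observed |mass|.
    """
    a = np.atleast_2d(np.asarray(series_a, dtype=float))
    b = np.atleast_2d(np.asarray(series_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("series_a and series_b must have identical shape (paired)")
    n_subj, n_samp = a.shape
    if n_subj < 6:
        raise ValueError(f"need >= 6 participants, got {n_subj}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    times_ms = np.asarray(times_ms, dtype=float)
    if times_ms.size != n_samp:
        raise ValueError("times_ms length must match the number of samples")

    diff = a - b
    threshold = float(sps.t.ppf(1 - cluster_alpha / 2, n_subj - 1))
    observed = _clusters_from_t(_sample_t(diff), threshold)

    rng = np.random.default_rng(seed)
    # vectorized sign-flip null of the max cluster mass
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        t_perm = _sample_t(diff * signs[p][:, None])
        cl = _clusters_from_t(t_perm, threshold)
        if cl:
            null_max[p] = max(abs(m) for _, _, m in cl)

    clusters = []
    for i, j, mass in observed:
        p_corr = (np.sum(null_max >= abs(mass)) + 1) / (n_perm + 1)
        clusters.append(
            Cluster(i, j, float(times_ms[i]), float(times_ms[j]), mass, float(p_corr))
        )
    return ClusterResult(
        clusters=clusters,
        threshold_t=threshold,
        cluster_alpha=cluster_alpha,
        corrected_alpha=corrected_alpha,
        n_perm=n_perm,
        seed=seed,
    )


def nearfar_interaction(
    near_a: np.ndarray,
    near_b: np.ndarray,
    far_a: np.ndarray,
    far_b: np.ndarray,
    times_ms: np.ndarray,
    **test_kwargs,
) -> tuple[np.ndarray, ClusterResult]:
    """Distance x avatar interaction contrast on per-participant GFP series.

    Per participant the interaction series is (near_a - near_b) - (far_a -
    far_b); it is tested against zero with the cluster permutation procedure.
    Returns (interaction series matrix, ClusterResult); the simple contrasts
    within significant windows are attached in ``extra``.
    """
    arrays = [np.atleast_2d(np.asarray(x, dtype=float)) for x in (near_a, near_b, far_a, far_b)]
    shapes = {x.shape for x in arrays}
    if len(shapes) != 1:
        raise ValueError("all four condition series must have identical shape")
    na, nb, fa, fb = arrays
    interaction = (na - nb) - (fa - fb)
    result = cluster_permutation_test(
        interaction, np.zeros_like(interaction), times_ms, **test_kwargs
    )
    simple = {}
    for c in result.significant():
        sl = slice(c.start_idx, c.end_idx + 1)
        simple[f"{c.start_ms:.0f}-{c.end_ms:.0f}ms"] = {
            "near_contrast_mean": float((na - nb)[:, sl].mean()),
            "far_contrast_mean": float((fa - fb)[:, sl].mean()),
        }
    result.extra["simple_contrasts_in_significant_windows"] = simple
    return interaction, result
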