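"""Behavioral peripersonal-space (PPS) facilitation gradient and extent.

Tactile reaction times are measured alone (unisensory, condition ``T``) or
while an avatar looms at one of five distances (visuo-tactile, ``VT``,
D1 = near .. D5 = far).  Per participant and session, VT mean RT at each
distance is normalized by the unisensory mean (nRT = VT/T); values below 1
indicate multisensory facilitation.  Across participants, a paired t-test per
distance (corrected over the five distances) flags significant facilitation,
and the PPS extent is the farthest distance d such that D1..d are all
significantly facilitated (contiguity from the body outward).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DISTANCES",
    "PPSExtentResult",
    "filter_trials",
    "normalize_rt",
    "pps_gradient_test",
    "holm_bonferroni",
]

DISTANCES = (1, 2, 3, 4, 5)


class DegenerateCellError(ValueError):
    """A participant x session x condition cell lost all its trials."""


@dataclass(frozen=True)
class PPSExtentResult:
    """Per-distance facilitation statistics and the contiguous PPS extent."""

    mean_nrt: dict[int, float]
    t_stat: dict[int, float]
    p_raw: dict[int, float]
    p_corrected: dict[int, float]
    significant: dict[int, bool]
    extent: int
    alpha: float
    correction: str
    n_participants: int
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_distance": {
                str(d): {
                    "mean_nrt": float(self.mean_nrt[d]),
                    "t": float(self.t_stat[d]),
                    "p_raw": float(self.p_raw[d]),
                    "p_corrected": float(self.p_corrected[d]),
                    "significant": bool(self.significant[d]),
                }
                for d in DISTANCES
            },
            "extent": int(self.extent),
            "alpha": self.alpha,
            "correction": self.correction,
            "n_participants": self.n_participants,
        }


def filter_trials(
    trials: pd.DataFrame, min_rt_ms: float = 100.0, max_rt_ms: float = 1000.0
) -> pd.DataFrame:
    """Drop anticipation/lapse trials outside [min_rt_ms, max_rt_ms].

    Raises :class:`DegenerateCellError` naming the participant if any
    participant x session x condition cell would lose all its trials.
    """
    if not min_rt_ms < max_rt_ms:
        raise ValueError("min_rt_ms must be < max_rt_ms")
    keep = (trials["rt_ms"] >= min_rt_ms) & (trials["rt_ms"] <= max_rt_ms)
    out = trials.loc[keep].copy()
    cells_before = trials.groupby(["participant_id", "session", "condition"]).size()
    cells_after = out.groupby(["participant_id", "session", "condition"]).size()
    lost = cells_before.index.difference(cells_after.index)
    if len(lost) > 0:
        pid, session, cond = lost[0]
        raise DegenerateCellError(
            f"all {cond} trials removed for participant {pid!r} in session {session!r}"
        )
    out.attrs["n_removed_per_participant"] = (
        trials.loc[~keep].groupby("participant_id").size().to_dict()
    )
    return out


def normalize_rt(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant x session, VT mean RT at each distance over the T mean.

    Returns a tidy profile table with columns participant_id, cohort, session,
    distance, nrt, vt_mean_ms, t_mean_ms, n_vt, n_t.
    """
    rows = []
    for (pid, session), grp in trials.groupby(["participant_id", "session"], sort=True):
        t_rt = grp.loc[grp["condition"] == "T", "rt_ms"]
        if t_rt.empty:
            raise DegenerateCellError(
                f"no unisensory (T) trials for participant {pid!r}, session {session!r}"
            )
        t_mean = t_rt.mean()
        vt = grp[grp["condition"] == "VT"]
        cohort = grp["cohort"].iloc[0] if "cohort" in grp else None
        for d in DISTANCES:
            cell = vt.loc[vt["distance"] == d, "rt_ms"]
            if cell.empty:
                raise DegenerateCellError(
                    f"no VT trials at distance D{d} for participant {pid!r}, "
                    f"session {session!r}"
                )
            rows.append(
                {
                    "participant_id": pid,
                    "cohort": cohort,
                    "session": session,
                    "distance": d,
                    "nrt": cell.mean() / t_mean,
                    "vt_mean_ms": cell.mean(),
                    "t_mean_ms": t_mean,
                    "n_vt": len(cell),
                    "n_t": len(t_rt),
                }
            )
    return pd.DataFrame(rows)


def holm_bonferroni(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, val)
        adj[idx] = running_max
    return adj


_CORRECTIONS = {
    "holm": holm_bonferroni,
    "bonferroni": lambda p: np.minimum(1.0, np.asarray(p, float) * len(p)),
    "none": lambda p: np.asarray(p, float),
}


def pps_gradient_test(
    profiles: pd.DataFrame, alpha: float = 0.05, correction: str = "holm"
) -> PPSExtentResult:
    """Test facilitation at each distance and derive the PPS extent.

    Per distance, a two-sided paired t-test of VT mean RT against T mean RT
    across participants; a distance counts as facilitated only when the
    corrected p is below alpha AND the mean normalized RT is below 1 (the
    direction gate).  Extent = largest d with D1..d all facilitated.
    """
    if correction not in _CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    pivot_vt = profiles.pivot_table(index="participant_id", columns="distance", values="vt_mean_ms")
    pivot_t = profiles.pivot_table(index="participant_id", columns="distance", values="t_mean_ms")
    pivot_nrt = profiles.pivot_table(index="participant_id", columns="distance", values="nrt")
    n = len(pivot_vt)
    if n < 3:
        raise ValueError(f"need >= 3 participants, got {n}")
    t_stats, p_raw, mean_nrt = {}, {}, {}
    for d in DISTANCES:
        res = sps.ttest_rel(pivot_vt[d], pivot_t[d])
        t_stats[d] = float(res.statistic)
        p_raw[d] = float(res.pvalue)
        mean_nrt[d] = float(pivot_nrt[d].mean())
    p_corr = _CORRECTIONS[correction](np.array([p_raw[d] for d in DISTANCES]))
    p_corrected = {d: float(p_corr[i]) for i, d in enumerate(DISTANCES)}
    significant = {
        d: bool(p_corrected[d] < alpha and mean_nrt[d] < 1.0) for d in DISTANCES
    }
    extent = 0
    for d in DISTANCES:
        if significant[d]:
            extent = d
        else:
            break
    return PPSExtentResult(
        mean_nrt=mean_nrt,
        t_stat=t_stats,
        p_raw=p_raw,
        p_corrected=p_corrected,
        significant=significant,
        extent=extent,
        alpha=alpha,
        correction=correction,
        n_participants=n,
    )
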