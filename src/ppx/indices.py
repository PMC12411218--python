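"""Composite ("synthetic") indices from post-minus-baseline marker panels.

A marker family (ILC subset frequencies, activation-marker positivity, or a
serum mediator family) is summarized per participant by the score on the
first principal component of the z-scored post-baseline changes.  PCA runs on
the correlation matrix because the features live on heterogeneous scales
(percent positivity vs. concentrations), and the component sign is fixed so
the largest-magnitude loading is positive — a deterministic, label-blind
convention recorded in the output.

The eigendecomposition is done explicitly here (rather than delegated to a
PCA library) so the variance accounting and sign rule are exactly the ones
documented; tests cross-check the loadings against an independent route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SyntheticIndex", "compute_delta", "synthetic_index"]

#: columns identifying a participant in a tidy panel table
ID_COLS = ["participant_id", "cohort"]


@dataclass(frozen=True)
class SyntheticIndex:
    """First-principal-component summary of a delta panel.

    scores is indexed by participant; loadings by feature name and unit-norm;
    variance_explained is lambda_1 / sum(lambda) of the correlation matrix.
    """

    scores: pd.Series
    loadings: pd.Series
    variance_explained: float
    sign_convention: str = "largest-|loading| positive"
    n_dropped_missing: int = 0
    more_features_than_participants: bool = False
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "loadings": {k: float(v) for k, v in self.loadings.items()},
            "variance_explained": float(self.variance_explained),
            "sign_convention": self.sign_convention,
            "n_dropped_missing": self.n_dropped_missing,
            "more_features_than_participants": self.more_features_than_participants,
        }


def _feature_cols(panel: pd.DataFrame) -> list[str]:
    meta = set(ID_COLS + ["timepoint", "family"])
    return [c for c in panel.columns if c not in meta]


def compute_delta(post: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """Element-wise post - baseline feature changes, matched by participant.

    Both tables are tidy panels with ``participant_id``/``cohort`` identifier
    columns and one column per feature.  Raises on unmatched participants or
    feature sets.
    """
    feats_post, feats_base = _feature_cols(post), _feature_cols(baseline)
    if set(feats_post) != set(feats_base):
        diff = sorted(set(feats_post) ^ set(feats_base))
        raise ValueError(f"feature mismatch between timepoints: {diff}")
    post_i = post.set_index("participant_id")
    base_i = baseline.set_index("participant_id")
    if set(post_i.index) != set(base_i.index):
        diff = sorted(set(post_i.index) ^ set(base_i.index))
        raise ValueError(f"unmatched participants between timepoints: {diff}")
    base_i = base_i.loc[post_i.index]
    delta = post_i[feats_post] - base_i[feats_post]
    out = delta.reset_index()
    out.insert(1, "cohort", post_i["cohort"].to_numpy())
    return out


def synthetic_index(deltas: pd.DataFrame) -> SyntheticIndex:
    """First-PCA-component index of a delta panel.

    Features are z-scored across participants (all cohorts together), the
    correlation matrix is eigendecomposed, and scores are the projections on
    the leading eigenvector.
    """
    feats = _feature_cols(deltas)
    if not feats:
        raise ValueError("no feature columns in delta panel")
    work = deltas.dropna(subset=feats)
    n_dropped = len(deltas) - len(work)
    x = work[feats].to_numpy(dtype=float)
    n, p = x.shape
    if n < 3:
        raise ValueError(f"need >= 3 complete participants, got {n}")
    sd = x.std(axis=0, ddof=1)
    zero_var = [feats[j] for j in np.flatnonzero(sd == 0)]
    if zero_var:
        raise ValueError(f"zero-variance feature(s): {zero_var}")
    z = (x - x.mean(axis=0)) / sd
    corr = (z.T @ z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    v1 = eigvecs[:, 0]
    # deterministic sign: the loading with the largest magnitude is positive;
    # ties broken by the first such feature in column order
    j = int(np.argmax(np.abs(v1)))
    if v1[j] < 0:
        v1 = -v1
    scores = z @ v1
    var_explained = float(eigvals[0] / eigvals.sum())
    return SyntheticIndex(
        scores=pd.Series(scores, index=work["participant_id"].to_numpy(), name="score"),
        loadings=pd.Series(v1, index=feats, name="loading"),
        variance_explained=var_explained,
        n_dropped_missing=int(n_dropped),
        more_features_than_participants=p > n,
        extra={"eigenvalues": eigvals.tolist()},
    )


def index_table(index: SyntheticIndex, deltas: pd.DataFrame) -> pd.DataFrame:
    """Tidy (participant, cohort, score) table for an index."""
    cohorts = deltas.set_index("participant_id")["cohort"]
    return pd.DataFrame(
        {
            "participant_id": index.scores.index,
            "cohort": cohorts.loc[index.scores.index].to_numpy(),
            "score": index.scores.to_numpy(),
        }
    )
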