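"""Shallow-network model of neuro-immune cross-talk.

Three per-participant mediator indices (HPA-related hormones ``h``,
eicosanoids ``e``, neuroinflammatory factors ``nf``) predict the composite
ILC-activation index through a single-hidden-layer network (tanh units,
linear output, L2 weight decay, full-batch quasi-Newton optimization with
seeded restarts).  The module provides:

* baseline univariate/multivariate linear regressions,
* leave-one-out cross-validation with fold-local standardization,
* the 2-D response surface over (hormones, eicosanoids) with the
  neuroinflammation input fixed at its sample mean, and the "hot spot"
  (region where predicted activation exceeds the mean measured activation),
* a 2x2 chi-square test of cohort membership inside/outside the hot spot,
* input-ablation re-runs and monotonicity/unimodality shape diagnostics.

Cohort labels never enter training; they are used only for post-hoc splits
(per-cohort regressions, the membership test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage import measure as skmeasure
from sklearn.neural_network import MLPRegressor

from .stats import StatResult, chi2_2x2

__all__ = [
    "INPUT_NAMES",
    "NetSpec",
    "TrainedNet",
    "LOOCVResult",
    "ResponseSurface",
    "HotSpotTest",
    "baseline_regressions",
    "fit_network",
    "loocv",
    "response_surface",
    "hotspot_membership_test",
    "ablation",
    "shape_diagnostics",
]

INPUT_NAMES = ("hormones", "eicosanoids", "neuroinflammation")


@dataclass(frozen=True)
class NetSpec:
    """Architecture and training configuration of the shallow network."""

    n_hidden: int = 5
    activation: str = "tanh"
    weight_decay: float = 0.3
    max_iter: int = 2000
    tol: float = 1e-7
    n_restarts: int = 10
    base_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_hidden": self.n_hidden,
            "activation": self.activation,
            "weight_decay": self.weight_decay,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "n_restarts": self.n_restarts,
            "base_seed": self.base_seed,
        }


@dataclass
class TrainedNet:
    """A fitted network plus the training-set standardization it used."""

    spec: NetSpec
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    model: MLPRegressor
    train_loss: float
    restart_chosen: int
    input_names: tuple[str, ...] = INPUT_NAMES

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z = (x - self.x_mean) / self.x_sd
        return self.model.predict(z) * self.y_sd + self.y_mean


@dataclass
class LOOCVResult:
    predictions: np.ndarray  # out-of-fold prediction per participant
    measured: np.ndarray
    variance_explained: float  # squared Pearson correlation
    r2_sse: float  # 1 - SSE/SST alternative
    per_cohort: dict  # cohort -> slope/intercept/r/p of measured on predicted
    spec: NetSpec


@dataclass
class ResponseSurface:
    axis1_name: str
    axis1_grid: np.ndarray
    axis2_name: str
    axis2_grid: np.ndarray
    fixed_name: str
    fixed_value: float
    predictions: np.ndarray  # shape (len(axis2_grid), len(axis1_grid))
    threshold: float
    mask: np.ndarray
    boundary: list  # list of (n_pts, 2) polylines in (axis1, axis2) units
    threshold_rule: str
    # central 95% range of the training data per axis; shape diagnostics are
    # read inside this window, where the fit is constrained by observations
    axis1_support: tuple[float, float] | None = None
    axis2_support: tuple[float, float] | None = None


@dataclass
class HotSpotTest:
    counts: np.ndarray  # 2x2: rows = cohorts, cols = (inside, outside)
    cohorts: tuple[str, str]
    result: StatResult
    membership: pd.Series  # participant_id -> bool


def _as_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be N x p with one row per y value")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in inputs")
    return X, y


def baseline_regressions(X, y) -> dict[str, StatResult]:
    """Ordinary least-squares baselines: one per input, plus all three jointly."""
    X, y = _as_xy(X, y)
    n, p = X.shape
    if n < 5:
        raise ValueError("need N >= 5")
    out: dict[str, StatResult] = {}
    names = INPUT_NAMES[:p] if p <= 3 else tuple(f"x{i+1}" for i in range(p))
    for j, name in enumerate(names):
        res = sps.linregress(X[:, j], y)
        out[f"univariate_{name}"] = StatResult(
            "linear_regression", float(res.slope), (n - 2,), float(res.pvalue),
            float(res.rvalue**2), "R2", (n,),
        )
    design = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float(((y - fitted) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    df1, df2 = p, n - p - 1
    f_stat = (r2 / df1) / ((1 - r2) / df2) if r2 < 1 else np.inf
    p_val = float(sps.f.sf(f_stat, df1, df2))
    out["multivariate"] = StatResult(
        "linear_regression", float(f_stat), (df1, df2), p_val, float(r2), "R2",
        (n,), extra={"rank_deficient": rank < p + 1, "coefficients": beta.tolist()},
    )
    return out


def fit_network(X, y, spec: NetSpec = NetSpec()) -> TrainedNet:
    """Fit the shallow network; best of ``n_restarts`` seeded initializations.

    Inputs and output are standardized with training statistics; the fit
    minimizes MSE plus ``weight_decay`` times the squared weight norm with
    L-BFGS.  Fully deterministic given (data, spec).
    """
    X, y = _as_xy(X, y)
    if X.shape[0] < 10:
        raise ValueError("need N >= 10 to fit the network")
    y_sd = y.std(ddof=0)
    if y_sd == 0:
        raise ValueError("zero-variance target: standardization undefined")
    x_mean, x_sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    if np.any(x_sd == 0):
        raise ValueError("zero-variance input column")
    z = (X - x_mean) / x_sd
    t = (y - y.mean()) / y_sd

    best: MLPRegressor | None = None
    best_loss, best_idx = np.inf, -1
    for r in range(spec.n_restarts):
        model = MLPRegressor(
            hidden_layer_sizes=(spec.n_hidden,),
            activation=spec.activation,
            solver="lbfgs",
            alpha=spec.weight_decay,
            max_iter=spec.max_iter,
            tol=spec.tol,
            random_state=spec.base_seed + r,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(z, t)
        if model.loss_ < best_loss:
            best, best_loss, best_idx = model, float(model.loss_), r
    assert best is not None
    return TrainedNet(
        spec=spec, x_mean=x_mean, x_sd=x_sd, y_mean=float(y.mean()),
        y_sd=float(y_sd), model=best, train_loss=best_loss, restart_chosen=best_idx,
    )


def loocv(X, y, spec: NetSpec = NetSpec(), cohorts=None) -> LOOCVResult:
    """Leave-one-out cross-validation with fold-local standardization.

    Participant i's prediction comes from a network trained without i.
    Variance explained is the squared Pearson correlation between out-of-fold
    predictions and measurements (the 1 - SSE/SST alternative is reported
    too).  Per-cohort regressions of measured on predicted are post hoc only.
    """
    X, y = _as_xy(X, y)
    n = X.shape[0]
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        net = fit_network(X[mask], y[mask], spec)
        preds[i] = net.predict(X[i : i + 1])[0]
    r = sps.pearsonr(preds, y).statistic if np.std(preds) > 0 else 0.0
    sst = float(((y - y.mean()) ** 2).sum())
    r2_sse = 1.0 - float(((y - preds) ** 2).sum()) / sst if sst > 0 else 0.0
    per_cohort = {}
    if cohorts is not None:
        cohorts = np.asarray(cohorts)
        for c in pd.unique(cohorts):
            sel = cohorts == c
            if sel.sum() >= 3 and np.std(preds[sel]) > 0:
                reg = sps.linregress(preds[sel], y[sel])
                per_cohort[str(c)] = {
                    "slope": float(reg.slope),
                    "intercept": float(reg.intercept),
                    "r": float(reg.rvalue),
                    "p": float(reg.pvalue),
                    "n": int(sel.sum()),
                }
    return LOOCVResult(
        predictions=preds, measured=y, variance_explained=float(r**2),
        r2_sse=r2_sse, per_cohort=per_cohort, spec=spec,
    )


def response_surface(
    net: TrainedNet,
    X,
    y,
    grid_n: int = 101,
    *,
    threshold_rule: str = "mean_measured",
    pad_sd: float = 0.5,
) -> ResponseSurface:
    """Predicted activation over the hormone x eicosanoid plane.

    The neuroinflammation input is fixed at its sample mean; the grid covers
    the observed range of each axis padded by ``pad_sd`` standard deviations.
    The hot spot is where predictions strictly exceed the threshold (mean
    measured activation by default; mean of grid predictions by flag).
    """
    X, y = _as_xy(X, y)
    if grid_n < 25:
        raise ValueError("grid_n must be >= 25")
    h, e, nf = X[:, 0], X[:, 1], X[:, 2]
    g1 = np.linspace(h.min() - pad_sd * h.std(), h.max() + pad_sd * h.std(), grid_n)
    g2 = np.linspace(e.min() - pad_sd * e.std(), e.max() + pad_sd * e.std(), grid_n)
    nf_mean = float(nf.mean())
    hh, ee = np.meshgrid(g1, g2)
    pts = np.column_stack([hh.ravel(), ee.ravel(), np.full(hh.size, nf_mean)])
    preds = net.predict(pts).reshape(hh.shape)
    if threshold_rule == "mean_measured":
        threshold = float(np.mean(y))
    elif threshold_rule == "mean_grid":
        threshold = float(preds.mean())
    else:
        raise ValueError(f"unknown threshold_rule {threshold_rule!r}")
    mask = preds > threshold
    boundary = []
    for contour in skmeasure.find_contours(preds.astype(float), threshold):
        # contour rows are (row=axis2 idx, col=axis1 idx) -> map to data units
        a1 = np.interp(contour[:, 1], np.arange(grid_n), g1)
        a2 = np.interp(contour[:, 0], np.arange(grid_n), g2)
        boundary.append(np.column_stack([a1, a2]))
    return ResponseSurface(
        axis1_name=INPUT_NAMES[0], axis1_grid=g1,
        axis2_name=INPUT_NAMES[1], axis2_grid=g2,
        fixed_name=INPUT_NAMES[2], fixed_value=nf_mean,
        predictions=preds, threshold=threshold, mask=mask,
        boundary=boundary, threshold_rule=threshold_rule,
        axis1_support=tuple(np.quantile(h, [0.025, 0.975])),
        axis2_support=tuple(np.quantile(e, [0.025, 0.975])),
    )


def hotspot_membership_test(
    surface: ResponseSurface,
    net: TrainedNet,
    data: pd.DataFrame,
) -> HotSpotTest:
    """Chi-square test of cohort membership inside the activation hot spot.

    ``data`` needs columns participant_id, cohort, hormones, eicosanoids;
    membership is evaluated at (h_i, e_i, mean nf) — the same 2-D convention
    as the surface — against the surface threshold.
    """
    cohorts = pd.unique(data["cohort"])
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts")
    pts = np.column_stack(
        [
            data["hormones"].to_numpy(float),
            data["eicosanoids"].to_numpy(float),
            np.full(len(data), surface.fixed_value),
        ]
    )
    inside = net.predict(pts) > surface.threshold
    membership = pd.Series(inside, index=data["participant_id"].to_numpy())
    counts = np.zeros((2, 2), dtype=int)
    for i, c in enumerate(cohorts[:2]):
        sel = (data["cohort"] == c).to_numpy()
        counts[i, 0] = int(np.sum(inside & sel))
        counts[i, 1] = int(np.sum(~inside & sel))
    try:
        result = chi2_2x2(counts)
    except ValueError as err:
        raise ValueError(
            "hot-spot membership chi-square undefined: every participant falls "
            "on the same side of the hot-spot boundary "
            f"(counts={counts.tolist()})"
        ) from err
    return HotSpotTest(
        counts=counts, cohorts=(str(cohorts[0]), str(cohorts[1])),
        result=result, membership=membership,
    )


def ablation(X, y, spec: NetSpec = NetSpec(), cohorts=None) -> dict[str, dict]:
    """LOOCV with each input removed in turn; reports delta R2 vs. full model."""
    X, y = _as_xy(X, y)
    full = loocv(X, y, spec, cohorts)
    out = {
        "full": {"variance_explained": full.variance_explained, "result": full}
    }
    names = INPUT_NAMES[: X.shape[1]]
    for j, name in enumerate(names):
        reduced = loocv(np.delete(X, j, axis=1), y, spec, cohorts)
        out[f"without_{name}"] = {
            "variance_explained": reduced.variance_explained,
            "delta_r2": full.variance_explained - reduced.variance_explained,
            "result": reduced,
        }
    return out


def shape_diagnostics(
    surface: ResponseSurface,
    net: TrainedNet | None = None,
    *,
    unimodal_tol: float = 0.05,
) -> dict:
    """Monotonicity and unimodality of the fitted response.

    Diagnostics are evaluated inside the surface's data-support window (the
    central 95% of each input), not over extrapolated grid padding.
    Spearman correlation of predictions with each axis (averaged over the
    other axis); unimodality of the eicosanoid profile (averaged over the
    hormone axis) = a single rise-then-fall derivative sign change, ignoring
    wiggles below ``unimodal_tol`` times the profile range.  If ``net`` is
    given, a 1-D sweep over neuroinflammation at mean hormones/eicosanoids is
    diagnosed the same way.
    """
    def _window(grid, support):
        if support is None:
            return np.ones(grid.size, dtype=bool)
        return (grid >= support[0]) & (grid <= support[1])

    keep1 = _window(surface.axis1_grid, surface.axis1_support)
    keep2 = _window(surface.axis2_grid, surface.axis2_support)
    preds = surface.predictions[np.ix_(keep2, keep1)]
    g1, g2 = surface.axis1_grid[keep1], surface.axis2_grid[keep2]
    n2, n1 = preds.shape
    rho_axis1 = float(
        np.mean([sps.spearmanr(g1, preds[i]).statistic
                 if np.ptp(preds[i]) > 0 else 0.0 for i in range(n2)])
    )
    rho_axis2 = float(
        np.mean([sps.spearmanr(g2, preds[:, j]).statistic
                 if np.ptp(preds[:, j]) > 0 else 0.0 for j in range(n1)])
    )
    # eicosanoid profile averaged over the hormone axis: the average keeps a
    # planted additive bump while damping fit noise in any single column
    profile = preds.mean(axis=1)
    out = {
        "monotonicity_hormones": rho_axis1,
        "monotonicity_eicosanoids": rho_axis2,
        "eicosanoid_profile_unimodal": _is_unimodal(profile, unimodal_tol),
    }
    if net is not None:
        nf_grid = np.linspace(
            surface.fixed_value - 2.0, surface.fixed_value + 2.0, n1
        )
        pts = np.column_stack(
            [
                np.full(n1, surface.axis1_grid.mean()),
                np.full(n1, surface.axis2_grid.mean()),
                nf_grid,
            ]
        )
        sweep = net.predict(pts)
        out["monotonicity_neuroinflammation"] = (
            float(sps.spearmanr(nf_grid, sweep).statistic) if np.ptp(sweep) > 0 else 0.0
        )
    return out


def _is_unimodal(profile: np.ndarray, tol: float) -> bool:
    """True for a rise-then-fall profile with an interior peak.

    The profile must rise to its maximum and fall afterwards, allowing
    monotonicity violations (dips on the way up, bumps on the way down) of at
    most ``tol`` times the profile range; the peak must be interior and
    prominent (above both endpoints by more than the tolerance).
    """
    profile = np.asarray(profile, dtype=float)
    rng_ = float(np.ptp(profile))
    if rng_ == 0:
        return False
    band = tol * rng_
    k = int(np.argmax(profile))
    if profile[k] - profile[0] <= band or profile[k] - profile[-1] <= band:
        return False  # peak at (or indistinguishable from) an endpoint
    rise, fall = profile[: k + 1], profile[k:]
    dip = float(np.max(np.maximum.accumulate(rise) - rise))
    bump = float(np.max(fall - np.minimum.accumulate(fall)))
    return dip <= band and bump <= band


def with_seed(spec: NetSpec, seed: int) -> NetSpec:
    """Convenience: the same spec with a different base seed."""
    return replace(spec, base_seed=seed)
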