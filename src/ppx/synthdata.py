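"""Seeded synthetic cohort generator and tidy-table I/O.

The generator emulates a four-cohort (neutral / infection / fearful /
vaccine) study of behavioral, electrophysiological and immune responses to
looming avatar stimuli, with two blood timepoints 120 min apart.  It plants
known ground truth at every level so downstream estimators can be verified:

* **Reaction times** — participant-level lognormal base RT (right-skewed, as
  empirical RT distributions are), with an additive negative shift at
  visuo-tactile distances inside a planted peripersonal-space boundary.
* **Immune panels** — ILC subset composition on a softmax (logit) scale so
  ILC1+ILC2+ILCP always sums to 100% of ILCs, and activation-marker
  positivity deltas driven by a latent activation score.
* **Serum mediators** — three families (HPA-related hormones, eicosanoids,
  13 named neuroinflammatory factors) whose post-baseline changes load on one
  latent index per family (h, e, nf).
* **Outcome** — the latent ILC activation score is a known nonlinear function
  of the three mediator latents:
  ``act = beta_h*h - beta_nf*nf + beta_e*exp(-(e-e0)^2/(2*sigma_e^2)) + noise``
  (linear up in hormones, linear down in neuroinflammation, Gaussian-tuned in
  eicosanoids).  Infection and vaccine cohorts receive configured mean shifts
  of the latents (hormones up, neuroinflammation down, eicosanoids toward the
  Gaussian peak), so immune modulation follows infection ~ vaccine > neutral
  ~ fearful.
* **EEG** — per-participant evoked channel x time matrices for near/far x
  avatar conditions with an effect of configurable amplitude planted in a
  known time window of the far-infectious condition.

Ground truth (latents, planted boundaries, planted EEG window, outcome
parameters) is returned alongside the data and is intended for tests only —
no analysis operation reads it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COHORTS",
    "BLOOD_ONLY_COHORTS",
    "NEUROINFLAMMATION_FACTORS",
    "ACTIVATION_MARKERS",
    "OutcomeParams",
    "EEGParams",
    "GeneratorConfig",
    "GroundTruth",
    "CohortData",
    "generate_cohort",
    "read_table",
    "write_table",
    "SCHEMAS",
    "SchemaError",
]

COHORTS = ("neutral", "infection", "fearful", "vaccine")
#: the vaccine cohort contributes blood samples only (no VR task, no EEG)
BLOOD_ONLY_COHORTS = ("vaccine",)
#: cohorts whose planted latent shifts emulate a (virtual or real) infection
SHIFTED_COHORTS = ("infection", "vaccine")

ACTIVATION_MARKERS = (
    "CD25", "CD27", "CD69", "NKp30", "NKp44", "NKp46", "KLRG1", "PD1", "HLA-DR",
)
NEUROINFLAMMATION_FACTORS = (
    "VILIP-1", "CCL2", "sTREM-2", "BDNF", "TGFb1", "VEGF", "IL-6",
    "sTREM-1", "b-NGF", "IL-18", "TNF", "sRAGE", "CX3CL1",
)
ILC_SUBSETS = ("ILC1", "ILC2", "ILCP")
SESSIONS = ("baseline", "second")
DISTANCES = (1, 2, 3, 4, 5)
DELAYS = (1, 2, 3, 4, 5)


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class OutcomeParams:
    """Parameters of the ground-truth ILC-activation function of (h, e, nf)."""

    beta_h: float = 1.2
    beta_nf: float = 0.8
    beta_e: float = 3.4
    e0: float = 0.3
    sigma_e: float = 0.8
    noise_sd: float = 0.25

    def evaluate(self, h, e, nf):
        h, e, nf = (np.asarray(v, dtype=float) for v in (h, e, nf))
        gauss = np.exp(-((e - self.e0) ** 2) / (2.0 * self.sigma_e**2))
        return self.beta_h * h - self.beta_nf * nf + self.beta_e * gauss


@dataclass(frozen=True)
class EEGParams:
    """Synthetic evoked-response geometry and the planted far-space effect."""

    n_channels: int = 16
    sfreq_hz: float = 256.0
    tmin_ms: float = -100.0
    tmax_ms: float = 400.0
    effect_window_ms: tuple[float, float] = (129.0, 150.0)
    effect_amp_uv: float = 1.5
    noise_amp_uv: float = 1.5


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort, with study-design defaults.

    Effect-size fields are standardized mean shifts applied to the infection
    and vaccine cohorts; setting them (and the facilitation/EEG amplitudes)
    to zero yields a global null for calibration runs.
    """

    n_per_cohort: int = 15
    seed: int = 0
    # reaction-time model
    rt_base_ms: float = 400.0
    rt_sd_ms: float = 40.0
    facilitation_ms: float = -30.0
    n_t_trials: int = 25
    n_vt_reps: int = 2
    pps_boundary: dict = field(
        default_factory=lambda: {
            "neutral": {"baseline": 2, "second": 2},
            "infection": {"baseline": 2, "second": 4},
            "fearful": {"baseline": 2, "second": 2},
        }
    )
    # mediator latent shifts (standardized units) for infection/vaccine
    mediator_effect_sizes: dict = field(
        default_factory=lambda: {
            "hormones": 1.9,
            "eicosanoids": 0.15,   # intermediate: toward the Gaussian peak e0
            "neuroinflammation": -1.2,
        }
    )
    # immune couplings: subset-composition logit shift per unit activation,
    # and marker-delta loading scale (percentage points per unit activation)
    immune_effect_sizes: dict = field(
        default_factory=lambda: {
            "ILC1": -0.35,
            "ILC2": 0.20,
            "ILCP": 0.15,
            "activation": 2.5,
        }
    )
    n_hormones: int = 8
    n_eicosanoids: int = 20
    mediator_loading_sd: float = 1.0
    mediator_noise_sd: float = 0.8
    outcome_params: OutcomeParams = field(default_factory=OutcomeParams)
    eeg_params: EEGParams = field(default_factory=EEGParams)
    include_rt: bool = True
    include_eeg: bool = True

    def __post_init__(self) -> None:
        if self.n_per_cohort < 3:
            raise ConfigError("n_per_cohort must be >= 3")
        if self.rt_base_ms <= 0 or self.rt_sd_ms <= 0:
            raise ConfigError("rt_base_ms and rt_sd_ms must be positive")
        if self.outcome_params.sigma_e <= 0:
            raise ConfigError("sigma_e must be > 0")
        if self.outcome_params.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.eeg_params.n_channels < 2:
            raise ConfigError("need at least 2 EEG channels")

    @staticmethod
    def null(seed: int = 0, **overrides) -> "GeneratorConfig":
        """A configuration with every planted effect removed (global null)."""
        defaults = dict(
            seed=seed,
            facilitation_ms=0.0,
            pps_boundary={
                c: {"baseline": 0, "second": 0}
                for c in ("neutral", "infection", "fearful")
            },
            mediator_effect_sizes={
                "hormones": 0.0, "eicosanoids": 0.0, "neuroinflammation": 0.0
            },
            eeg_params=EEGParams(effect_amp_uv=0.0),
        )
        defaults.update(overrides)
        return GeneratorConfig(**defaults)


@dataclass
class GroundTruth:
    """Planted quantities, for verification only — never read by analyses."""

    latents: pd.DataFrame  # participant_id, cohort, h, e, nf, activation
    outcome_params: OutcomeParams
    pps_boundary: dict
    eeg_effect_window_ms: tuple[float, float]
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "latents": self.latents.to_dict(orient="list"),
                "outcome_params": asdict(self.outcome_params),
                "pps_boundary": self.pps_boundary,
                "eeg_effect_window_ms": list(self.eeg_effect_window_ms),
                "seed": self.seed,
            },
            sort_keys=True,
        )


@dataclass
class CohortData:
    """Everything one generator run produces."""

    trials: pd.DataFrame  # RT trials (VR cohorts only)
    markers: dict  # panel name -> {"baseline": df, "post": df}
    mediators: dict  # family -> {"baseline": df, "post": df}
    eeg: dict  # (participant_id, condition) -> channels x samples array
    eeg_times_ms: np.ndarray
    truth: GroundTruth


def _participant_ids(cohort: str, n: int) -> list[str]:
    return [f"{cohort[:3]}{i:03d}" for i in range(1, n + 1)]


def _generate_trials(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    log_sd = np.log1p(cfg.rt_sd_ms / cfg.rt_base_ms)
    n_vt = len(DISTANCES) * len(DELAYS) * cfg.n_vt_reps
    n_cell = cfg.n_t_trials + n_vt  # trials per participant x session
    vt_dist = np.repeat(np.array(DISTANCES, float), len(DELAYS) * cfg.n_vt_reps)
    vt_delay = np.tile(np.repeat(DELAYS, cfg.n_vt_reps), len(DISTANCES))
    frames = []
    for cohort in COHORTS:
        if cohort in BLOOD_ONLY_COHORTS:
            continue
        bounds = cfg.pps_boundary.get(cohort, {"baseline": 0, "second": 0})
        pids = _participant_ids(cohort, cfg.n_per_cohort)
        base = cfg.rt_base_ms * np.exp(rng.normal(0, 0.08, len(pids)))
        for session in SESSIONS:
            boundary = int(bounds.get(session, 0))
            noise = np.exp(rng.normal(0, log_sd, (len(pids), n_cell)))
            rt = base[:, None] * noise
            shift = np.where(vt_dist <= boundary, cfg.facilitation_ms, 0.0)
            rt[:, cfg.n_t_trials:] = np.maximum(
                rt[:, cfg.n_t_trials:] + shift[None, :], 50.0
            )
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": np.repeat(pids, n_cell),
                        "cohort": cohort,
                        "session": session,
                        "condition": np.tile(
                            np.r_[["T"] * cfg.n_t_trials, ["VT"] * n_vt], len(pids)
                        ),
                        "distance": np.tile(
                            np.r_[np.full(cfg.n_t_trials, np.nan), vt_dist], len(pids)
                        ),
                        "delay_index": np.tile(
                            np.r_[np.arange(cfg.n_t_trials) % len(DELAYS) + 1,
                                  vt_delay], len(pids)
                        ).astype(int),
                        "rt_ms": rt.ravel(),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _mediator_features(cfg: GeneratorConfig) -> dict[str, list[str]]:
    return {
        "hormones": [f"hormone_{i+1:02d}" for i in range(cfg.n_hormones)],
        "eicosanoids": [f"eicosanoid_{i+1:02d}" for i in range(cfg.n_eicosanoids)],
        "neuroinflammation": list(NEUROINFLAMMATION_FACTORS),
    }


def _generate_blood(cfg: GeneratorConfig, rng: np.random.Generator):
    """Mediator panels, immune panels and the ground-truth latent table."""
    op = cfg.outcome_params
    ids, cohorts = [], []
    for cohort in COHORTS:
        pids = _participant_ids(cohort, cfg.n_per_cohort)
        ids.extend(pids)
        cohorts.extend([cohort] * len(pids))
    n = len(ids)
    shifted = np.array([c in SHIFTED_COHORTS for c in cohorts])

    latents = {}
    for fam in ("hormones", "eicosanoids", "neuroinflammation"):
        key = {"hormones": "h", "eicosanoids": "e", "neuroinflammation": "nf"}[fam]
        shift = cfg.mediator_effect_sizes.get(fam, 0.0)
        latents[key] = rng.normal(0, 1, n) + shift * shifted
    activation = op.evaluate(latents["h"], latents["e"], latents["nf"])
    activation = activation + rng.normal(0, op.noise_sd, n)

    truth = pd.DataFrame(
        {"participant_id": ids, "cohort": cohorts, **latents,
         "activation": activation}
    )

    # --- mediator concentration panels -----------------------------------
    feats = _mediator_features(cfg)
    mediators = {}
    fam_key = {"hormones": "h", "eicosanoids": "e", "neuroinflammation": "nf"}
    for fam, names in feats.items():
        latent = latents[fam_key[fam]]
        base_scale = rng.lognormal(mean=2.0, sigma=0.8, size=len(names))
        baseline = np.abs(
            base_scale[None, :] * (1.0 + 0.25 * rng.normal(0, 1, (n, len(names))))
        )
        loadings = np.abs(rng.normal(1.0, 0.3, len(names))) * cfg.mediator_loading_sd
        noise = rng.normal(0, cfg.mediator_noise_sd, (n, len(names)))
        delta_std = loadings[None, :] * latent[:, None] + noise
        post = np.maximum(baseline + 0.15 * base_scale[None, :] * delta_std, 0.0)
        cols = {"participant_id": ids, "cohort": cohorts}
        mediators[fam] = {
            "baseline": pd.DataFrame(
                {**cols, "timepoint": "baseline",
                 **{nm: baseline[:, j] for j, nm in enumerate(names)}}
            ),
            "post": pd.DataFrame(
                {**cols, "timepoint": "post",
                 **{nm: post[:, j] for j, nm in enumerate(names)}}
            ),
        }

    # --- immune marker panels --------------------------------------------
    eff = cfg.immune_effect_sizes
    # coupled activation score: shares the latent signal with the marker
    # deltas so frequency and activation indices correlate as in vivo
    act_c = activation + rng.normal(0, 0.3, n)

    base_logits = np.array([1.0, 0.3, 0.1]) + rng.normal(0, 0.25, (n, 3))
    post_logits = base_logits.copy()
    for j, subset in enumerate(ILC_SUBSETS):
        post_logits[:, j] += eff.get(subset, 0.0) * act_c + rng.normal(0, 0.1, n)

    def softmax_pct(logits):
        z = np.exp(logits - logits.max(axis=1, keepdims=True))
        return 100.0 * z / z.sum(axis=1, keepdims=True)

    base_pct = softmax_pct(base_logits)
    post_pct = softmax_pct(post_logits)
    total_base = np.abs(0.5 + 0.1 * rng.normal(0, 1, n))
    total_post = np.abs(total_base + 0.02 * act_c + 0.02 * rng.normal(0, 1, n))

    cols = {"participant_id": ids, "cohort": cohorts}
    markers = {}
    markers["ilc_frequency"] = {
        tp: pd.DataFrame(
            {**cols, "timepoint": tp,
             "total_ILC_pct_lymph": tot,
             **{f"{s}_pct_ILC": pct[:, j] for j, s in enumerate(ILC_SUBSETS)}}
        )
        for tp, pct, tot in (
            ("baseline", base_pct, total_base), ("post", post_pct, total_post)
        )
    }

    scale = eff.get("activation", 0.0)
    for panel, subset_gain in [("ilc_activation", 1.0),
                               ("ilc1_activation", 1.0),
                               ("ilc2_activation", 0.8),
                               ("ilcp_activation", 0.8)]:
        base_pos = np.clip(rng.uniform(5, 40, (n, len(ACTIVATION_MARKERS))), 0, 100)
        loadings = np.abs(rng.normal(1.0, 0.25, len(ACTIVATION_MARKERS)))
        noise = rng.normal(0, 1.0, (n, len(ACTIVATION_MARKERS)))
        delta = scale * subset_gain * (
            0.4 * loadings[None, :] * act_c[:, None] + 0.6 * noise
        )
        post_pos = np.clip(base_pos + delta, 0, 100)
        markers[panel] = {
            "baseline": pd.DataFrame(
                {**cols, "timepoint": "baseline",
                 **{m: base_pos[:, j] for j, m in enumerate(ACTIVATION_MARKERS)}}
            ),
            "post": pd.DataFrame(
                {**cols, "timepoint": "post",
                 **{m: post_pos[:, j] for j, m in enumerate(ACTIVATION_MARKERS)}}
            ),
        }
    return mediators, markers, truth


def _smooth_noise(rng, shape, kernel: int = 7):
    """Temporally smoothed Gaussian noise (moving-average filtered)."""
    from scipy.ndimage import uniform_filter1d

    x = rng.normal(0, 1, shape)
    return uniform_filter1d(x, kernel, axis=-1, mode="constant")


def _generate_eeg(cfg: GeneratorConfig, rng: np.random.Generator):
    p = cfg.eeg_params
    n_samp = int(round((p.tmax_ms - p.tmin_ms) * p.sfreq_hz / 1000.0)) + 1
    times = p.tmin_ms + np.arange(n_samp) * 1000.0 / p.sfreq_hz
    # shared evoked waveform: two components at ~100 ms and ~200 ms
    erp = 3.0 * np.exp(-((times - 100) ** 2) / (2 * 20**2)) - 2.0 * np.exp(
        -((times - 200) ** 2) / (2 * 35**2)
    )
    topo = rng.normal(0, 1, (p.n_channels,))
    topo -= topo.mean()  # zero-mean topography so GFP sees the full pattern
    effect_topo = rng.normal(0, 1, (p.n_channels,))
    effect_topo -= effect_topo.mean()
    effect_topo /= np.linalg.norm(effect_topo) / np.sqrt(p.n_channels)
    in_window = (times >= p.effect_window_ms[0]) & (times <= p.effect_window_ms[1])

    conditions = ("T", "VT_near_A", "VT_near_B", "VT_far_A", "VT_far_B")
    eeg = {}
    for cohort in COHORTS:
        if cohort in BLOOD_ONLY_COHORTS:
            continue
        for pid in _participant_ids(cohort, cfg.n_per_cohort):
            gain = 1.0 + 0.2 * rng.normal()
            for cond in conditions:
                v = gain * np.outer(topo, erp)
                v = v + p.noise_amp_uv * _smooth_noise(rng, (p.n_channels, n_samp))
                # planted avatar-specific effect: infection cohort, far space,
                # avatar B (infectious), inside the known window
                if cohort == "infection" and cond == "VT_far_B":
                    v = v + p.effect_amp_uv * np.outer(effect_topo, in_window.astype(float))
                eeg[(pid, cond)] = v
    return eeg, times


def generate_cohort(config: GeneratorConfig) -> CohortData:
    """Generate a full synthetic study; identical config => identical output."""
    rng = np.random.default_rng(config.seed)
    trials = (
        _generate_trials(config, rng)
        if config.include_rt
        else pd.DataFrame(
            columns=["participant_id", "cohort", "session", "condition",
                     "distance", "delay_index", "rt_ms"]
        )
    )
    mediators, markers, truth_latents = _generate_blood(config, rng)
    if config.include_eeg:
        eeg, times = _generate_eeg(config, rng)
    else:
        eeg, times = {}, np.array([])
    truth = GroundTruth(
        latents=truth_latents,
        outcome_params=config.outcome_params,
        pps_boundary=config.pps_boundary,
        eeg_effect_window_ms=config.eeg_params.effect_window_ms,
        seed=config.seed,
    )
    return CohortData(
        trials=trials, markers=markers, mediators=mediators,
        eeg=eeg, eeg_times_ms=times, truth=truth,
    )


# ---------------------------------------------------------------------------
# tidy-table I/O with schema validation
# ---------------------------------------------------------------------------

class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


#: required columns and numeric columns per known table schema
SCHEMAS: dict[str, dict] = {
    "trials": {
        "required": ["participant_id", "cohort", "session", "condition",
                     "distance", "delay_index", "rt_ms"],
        "numeric": ["distance", "delay_index", "rt_ms"],
        "key": ["participant_id", "session", "condition", "distance",
                "delay_index"],
    },
    "marker_panel": {
        "required": ["participant_id", "cohort", "timepoint"],
        "numeric": [],
        "key": ["participant_id", "timepoint"],
    },
    "mediator_panel": {
        "required": ["participant_id", "cohort", "timepoint"],
        "numeric": [],
        "key": ["participant_id", "timepoint"],
    },
    "index_table": {
        "required": ["participant_id", "cohort", "score"],
        "numeric": ["score"],
        "key": ["participant_id"],
    },
}


def _validate(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    spec = SCHEMAS[schema]
    for col in spec["required"]:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} for schema {schema!r}")
    numeric = spec["numeric"] or [
        c for c in df.columns if c not in spec["required"]
    ]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r} at row {row}"
            )
        df[col] = coerced
    return df


def write_table(table: pd.DataFrame, path: str | Path, schema: str) -> Path:
    """Write a tidy CSV after validating it against a named schema."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    _validate(table.copy(), schema)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a tidy CSV; raises :class:`SchemaError` on violations."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path)
    return _validate(df, schema)


def write_cohort_dir(data: CohortData, out_dir: str | Path) -> Path:
    """Write a full generated study to one directory of plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not data.trials.empty:
        write_table(data.trials, out / "trials.csv", "trials")
    for panel, tps in data.markers.items():
        for tp, df in tps.items():
            write_table(df, out / f"markers_{panel}_{tp}.csv", "marker_panel")
    for fam, tps in data.mediators.items():
        for tp, df in tps.items():
            write_table(df, out / f"mediators_{fam}_{tp}.csv", "mediator_panel")
    if data.eeg:
        eeg_dir = out / "eeg"
        eeg_dir.mkdir(exist_ok=True)
        for (pid, cond), mat in data.eeg.items():
            np.savetxt(eeg_dir / f"{pid}_{cond}.csv", mat, delimiter=",")
        (eeg_dir / "times_ms.csv").write_text(
            ",".join(f"{t:.6f}" for t in data.eeg_times_ms) + "\n"
        )
    (out / "ground_truth.json").write_text(data.truth.to_json() + "\n")
    return out
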