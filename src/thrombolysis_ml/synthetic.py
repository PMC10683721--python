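"""Synthetic stroke-audit data with known ground truth.

Emulates a national stroke-audit registry cohort of emergency
admissions arriving within 4 h of stroke onset: 10 patient/hospital
features plus a binary thrombolysis label. Labels are drawn from an
additive log-odds decision model whose per-feature effect shapes are
piecewise linear with fold-change spans taken from published registry
analyses (e.g. a 9-fold decline in odds over the first 120 min of
arrival-to-scan time, a 13-fold spread between hospitals). Because the
generating model is known exactly, every downstream stage — model fit,
SHAP decomposition, counterfactual cohorts, variance partitioning — can
be tested for recovery of the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EffectParams",
    "GeneratorConfig",
    "HospitalProfile",
    "TrueDecisionModel",
    "SchemaError",
    "FEATURE_COLUMNS",
    "LABEL_COLUMN",
    "AGE_MIDPOINTS",
    "sample_hospitals",
    "sample_patients",
    "true_log_odds",
    "assign_labels",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "validate_table",
]

#: The 10 model features, in selection order, plus the binary label.
FEATURE_COLUMNS = [
    "arrival_to_scan_min",
    "infarction",
    "nihss",
    "precise_onset",
    "prior_mrs",
    "stroke_team",
    "anticoagulant",
    "onset_to_arrival_min",
    "onset_during_sleep",
    "age_midpoint",
]
LABEL_COLUMN = "thrombolysis"

#: Midpoints of the 5-year age bands the registry reports (37.5 ... 92.5).
AGE_MIDPOINTS = np.arange(37.5, 95.0, 5.0)


class SchemaError(ValueError):
    """A table violates the patient-record schema; message names the column."""


@dataclass
class EffectParams:
    """Fold-change spans of the piecewise-linear per-feature log-odds effects.

    Each ``*_fold`` is an odds ratio (> 0) between the stated feature
    values; the generator converts it to a log-odds span. Defaults follow
    the magnitudes reported for the England & Wales registry.
    """

    arrival_to_scan_fold: float = 9.0     # odds drop over 0 -> 120 min
    arrival_to_scan_tail: float = 0.25    # relative slope beyond 120 min
    nihss_span_fold: float = 30.0         # odds rise NIHSS 0 -> plateau
    nihss_peak_lo: int = 15               # plateau start
    nihss_peak_hi: int = 25               # plateau end
    nihss_high_fold: float = 5.0          # odds drop plateau -> NIHSS 42
    precise_onset_fold: float = 3.0       # precise vs estimated onset time
    prior_mrs_fold: float = 6.0           # odds drop mRS 0 -> 5
    anticoagulant_fold: float = 5.0       # odds drop with anticoagulant use
    onset_to_arrival_fold: float = 3.0    # odds drop 120 -> 240 min
    sleep_fold: float = 4.0               # odds drop for onset during sleep
    age_fold: float = 2.0                 # odds drop age 80 -> 110

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if name.endswith("_fold") and not value > 0:
                raise ValueError(f"effect parameter {name} must be > 0")


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic registry generator.

    ``n_hospitals * patients_per_hospital`` patients are allocated to
    hospitals proportionally to their (log-normal) admission volumes.
    ``hospital_offset_span_fold`` fixes the extreme odds ratio between
    the most and least thrombolysis-prone hospitals; ``process_coupling``
    is the decrease in median scan-to-needle minutes per unit log-odds
    of hospital offset (prone hospitals treat faster).
    """

    n_hospitals: int = 30
    patients_per_hospital: int = 700
    seed: int = 0
    intercept: float = 2.6
    effect_params: EffectParams = field(default_factory=EffectParams)
    hospital_offset_sd: float = 0.6
    hospital_offset_span_fold: float = 13.0
    process_coupling: float = 8.0
    decoy_feature_count: int = 0
    # Feature marginals
    haemorrhage_prob: float = 0.15
    precise_onset_prob: float = 0.65
    anticoagulant_prob: float = 0.12
    sleep_prob: float = 0.10
    arrival_to_scan_log_mu: float = math.log(35.0)
    arrival_to_scan_log_sigma: float = 0.8
    arrival_to_scan_max: float = 360.0
    arrival_location_sd: float = 6.0
    onset_to_arrival_log_mu: float = math.log(100.0)
    onset_to_arrival_log_sigma: float = 0.45
    nihss_gamma_shape: float = 1.8
    nihss_gamma_scale: float = 5.0
    age_mean: float = 73.0
    age_sd: float = 13.0
    prior_mrs_base_logit: float = -2.0
    age_mrs_coupling: float = 0.48
    admissions_log_sigma: float = 0.4
    admissions_median: float = 650.0
    scan_to_needle_base: float = 40.0
    scan_to_needle_sd: float = 8.0

    def validate(self) -> None:
        if self.n_hospitals < 1:
            raise ValueError("n_hospitals must be >= 1")
        if self.patients_per_hospital < 1:
            raise ValueError("patients_per_hospital must be >= 1")
        if not self.hospital_offset_span_fold > 0:
            raise ValueError("hospital_offset_span_fold must be > 0")
        if self.decoy_feature_count < 0:
            raise ValueError("decoy_feature_count must be >= 0")
        self.effect_params.validate()


@dataclass
class HospitalProfile:
    """Ground truth for one stroke team.

    ``true_offset`` is the log-odds added to every patient attending the
    team; ``arrival_to_scan_location`` shifts the team's arrival-to-scan
    distribution (a process property that, unlike the offset, acts on a
    patient feature rather than directly on the decision).
    """

    team_id: str
    true_offset: float
    admissions_per_year: float
    median_scan_to_needle_min: float
    arrival_to_scan_location: float


@dataclass
class TrueDecisionModel:
    """The additive log-odds decision rule used to label synthetic patients.

    total log-odds = intercept + sum_k f_k(x_k) + hospital offset.
    Haemorrhagic stroke is handled outside the log-odds scale: the label
    is deterministically 0, mirroring clinical contraindication.
    """

    intercept: float
    effects: EffectParams
    offsets: dict[str, float]

    # -- per-feature piecewise-linear effects (log-odds) ------------------

    def f_arrival_to_scan(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        slope = math.log(self.effects.arrival_to_scan_fold) / 120.0
        return -(slope * np.minimum(t, 120.0)
                 + slope * self.effects.arrival_to_scan_tail
                 * np.maximum(t - 120.0, 0.0))

    def f_nihss(self, n: np.ndarray) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        lo, hi = self.effects.nihss_peak_lo, self.effects.nihss_peak_hi
        rise = math.log(self.effects.nihss_span_fold)
        fall = math.log(self.effects.nihss_high_fold)
        out = np.zeros_like(n)
        below = n < lo
        out[below] = -rise * (lo - n[below]) / lo
        above = n > hi
        out[above] = -fall * (n[above] - hi) / (42.0 - hi)
        return out

    def f_precise_onset(self, x: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(x) == 1, 0.0,
                        -math.log(self.effects.precise_onset_fold))

    def f_prior_mrs(self, m: np.ndarray) -> np.ndarray:
        return -math.log(self.effects.prior_mrs_fold) * np.asarray(m, float) / 5.0

    def f_anticoagulant(self, x: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(x) == 1,
                        -math.log(self.effects.anticoagulant_fold), 0.0)

    def f_onset_to_arrival(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return -math.log(self.effects.onset_to_arrival_fold) \
            * np.maximum(t - 120.0, 0.0) / 120.0

    def f_sleep(self, x: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(x) == 1, -math.log(self.effects.sleep_fold), 0.0)

    def f_age(self, a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        return -math.log(self.effects.age_fold) * np.maximum(a - 80.0, 0.0) / 30.0

    def feature_effects(self, table: pd.DataFrame) -> pd.DataFrame:
        """Per-feature log-odds contributions, one column per feature."""
        return pd.DataFrame({
            "arrival_to_scan_min": self.f_arrival_to_scan(table["arrival_to_scan_min"]),
            "nihss": self.f_nihss(table["nihss"]),
            "precise_onset": self.f_precise_onset(table["precise_onset"]),
            "prior_mrs": self.f_prior_mrs(table["prior_mrs"]),
            "anticoagulant": self.f_anticoagulant(table["anticoagulant"]),
            "onset_to_arrival_min": self.f_onset_to_arrival(table["onset_to_arrival_min"]),
            "onset_during_sleep": self.f_sleep(table["onset_during_sleep"]),
            "age_midpoint": self.f_age(table["age_midpoint"]),
        }, index=table.index)


def _domain_check(table: pd.DataFrame) -> None:
    """Raise SchemaError if any feature value is outside its declared domain."""
    checks = [
        ("arrival_to_scan_min", lambda s: (s >= 0) & np.isfinite(s)),
        ("infarction", lambda s: s.isin([0, 1])),
        ("nihss", lambda s: (s >= 0) & (s <= 42) & (s == s.astype(int))),
        ("precise_onset", lambda s: s.isin([0, 1])),
        ("prior_mrs", lambda s: (s >= 0) & (s <= 5) & (s == s.astype(int))),
        ("anticoagulant", lambda s: s.isin([0, 1])),
        ("onset_to_arrival_min", lambda s: (s > 0) & (s <= 240)),
        ("onset_during_sleep", lambda s: s.isin([0, 1])),
        ("age_midpoint", lambda s: s.isin(AGE_MIDPOINTS)),
    ]
    for col, ok in checks:
        if col not in table.columns:
            raise SchemaError(f"missing column: {col}")
        if len(table) and not ok(table[col]).all():
            raise SchemaError(f"out-of-domain value in column: {col}")
    if "stroke_team" not in table.columns:
        raise SchemaError("missing column: stroke_team")


def validate_table(table: pd.DataFrame, require_label: bool = True) -> None:
    """Validate the full patient-table schema.

    Raises
    ------
    SchemaError
        Naming the offending column (missing, out-of-domain, or a missing
        label column when ``require_label``).
    """
    unknown = [c for c in table.columns
               if c not in FEATURE_COLUMNS + [LABEL_COLUMN]
               and not c.startswith("decoy_")]
    if unknown:
        raise SchemaError(f"unknown column: {unknown[0]}")
    _domain_check(table)
    if require_label:
        if LABEL_COLUMN not in table.columns:
            raise SchemaError(f"missing column: {LABEL_COLUMN}")
        if len(table) and not table[LABEL_COLUMN].isin([0, 1]).all():
            raise SchemaError(f"out-of-domain value in column: {LABEL_COLUMN}")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named substreams spawned deterministically from one master seed."""
    names = ["hospitals", "patients", "labels", "decoys"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child)
            for name, child in zip(names, children)}


def sample_hospitals(config: GeneratorConfig) -> list[HospitalProfile]:
    """Draw hospital profiles with offsets rescaled to the target odds span.

    Offsets are drawn normal, then affinely rescaled so that
    ``exp(max - min) == hospital_offset_span_fold`` exactly and the mean
    offset is 0. With a single hospital the span is degenerate and the
    offset is 0. Median scan-to-needle time is negatively coupled to the
    offset with slope ``process_coupling`` (min per log-odds unit).
    """
    config.validate()
    rng = _streams(config.seed)["hospitals"]
    n = config.n_hospitals
    raw = rng.normal(0.0, config.hospital_offset_sd, size=n)
    if n == 1:
        offsets = np.zeros(1)
    else:
        span = raw.max() - raw.min()
        if span == 0:  # pathological draw; spread deterministically
            raw = np.linspace(-0.5, 0.5, n)
            span = 1.0
        scale = math.log(config.hospital_offset_span_fold) / span
        offsets = raw * scale
        offsets -= offsets.mean()
    admissions = config.admissions_median * np.exp(
        rng.normal(0.0, config.admissions_log_sigma, size=n))
    stn = np.clip(
        config.scan_to_needle_base - config.process_coupling * offsets
        + rng.normal(0.0, config.scan_to_needle_sd, size=n),
        5.0, None)
    locs = rng.normal(0.0, config.arrival_location_sd, size=n)
    width = len(str(n - 1))
    return [
        HospitalProfile(
            team_id=f"T{i:0{width}d}",
            true_offset=float(offsets[i]),
            admissions_per_year=float(admissions[i]),
            median_scan_to_needle_min=float(stn[i]),
            arrival_to_scan_location=float(locs[i]),
        )
        for i in range(n)
    ]


def _allocate_patients(config: GeneratorConfig,
                       hospitals: list[HospitalProfile],
                       rng: np.random.Generator) -> np.ndarray:
    """Patient counts per hospital: proportional to admissions, min 1 each."""
    total = config.n_hospitals * config.patients_per_hospital
    weights = np.array([h.admissions_per_year for h in hospitals], dtype=float)
    weights /= weights.sum()
    base = np.ones(len(hospitals), dtype=int)
    rest = total - len(hospitals)
    if rest < 0:
        raise ValueError("fewer patients than hospitals requested")
    counts = base + rng.multinomial(rest, weights)
    return counts


def sample_patients(config: GeneratorConfig,
                    hospitals: list[HospitalProfile],
                    n_patients: int | None = None) -> pd.DataFrame:
    """Sample an unlabelled patient table.

    Features are drawn independently except prior mRS, which increases
    mildly with age (``age_mrs_coupling``), and arrival-to-scan time,
    whose distribution is shifted per hospital. Onset-to-arrival times
    are truncated at the 4 h cut-off that defines the modelled cohort.

    Parameters
    ----------
    n_patients
        Override the total cohort size (defaults to
        ``n_hospitals * patients_per_hospital``). 0 yields an empty
        table with the full schema.
    """
    config.validate()
    if not hospitals:
        raise ValueError("hospital list must be non-empty")
    rng = _streams(config.seed)["patients"]
    decoy_rng = _streams(config.seed)["decoys"]

    if n_patients is None:
        counts = _allocate_patients(config, hospitals, rng)
    elif n_patients == 0:
        counts = np.zeros(len(hospitals), dtype=int)
    else:
        weights = np.array([h.admissions_per_year for h in hospitals])
        weights = weights / weights.sum()
        if n_patients >= len(hospitals):
            counts = np.ones(len(hospitals), dtype=int) + rng.multinomial(
                n_patients - len(hospitals), weights)
        else:
            counts = rng.multinomial(n_patients, weights)
    n = int(counts.sum())

    team = np.repeat([h.team_id for h in hospitals], counts)
    loc = np.repeat([h.arrival_to_scan_location for h in hospitals], counts)

    a2s = np.exp(rng.normal(config.arrival_to_scan_log_mu,
                            config.arrival_to_scan_log_sigma, n)) + loc
    a2s = np.clip(a2s, 0.0, config.arrival_to_scan_max)

    infarction = (rng.random(n) >= config.haemorrhage_prob).astype(int)
    nihss = np.clip(np.floor(rng.gamma(config.nihss_gamma_shape,
                                       config.nihss_gamma_scale, n)),
                    0, 42).astype(int)
    precise = (rng.random(n) < config.precise_onset_prob).astype(int)

    age_raw = rng.normal(config.age_mean, config.age_sd, n)
    band = np.clip(np.round((age_raw - 37.5) / 5.0), 0,
                   len(AGE_MIDPOINTS) - 1).astype(int)
    age = AGE_MIDPOINTS[band]

    # prior mRS rises with age: binomial(5, sigmoid(base + c * (age-70)/10))
    p_mrs = 1.0 / (1.0 + np.exp(-(config.prior_mrs_base_logit
                                  + config.age_mrs_coupling * (age - 70.0) / 10.0)))
    prior_mrs = rng.binomial(5, p_mrs)

    anticoag = (rng.random(n) < config.anticoagulant_prob).astype(int)

    # truncated lognormal on (0, 240]
    from scipy import stats
    dist = stats.lognorm(s=config.onset_to_arrival_log_sigma,
                         scale=math.exp(config.onset_to_arrival_log_mu))
    o2a = dist.ppf(rng.random(n) * dist.cdf(240.0)) if n else np.array([])
    o2a = np.clip(o2a, 1e-9, 240.0)

    sleep = (rng.random(n) < config.sleep_prob).astype(int)

    table = pd.DataFrame({
        "arrival_to_scan_min": a2s,
        "infarction": infarction,
        "nihss": nihss,
        "precise_onset": precise,
        "prior_mrs": prior_mrs,
        "stroke_team": pd.Series(team, dtype=str),
        "anticoagulant": anticoag,
        "onset_to_arrival_min": o2a,
        "onset_during_sleep": sleep,
        "age_midpoint": age,
    })
    for k in range(config.decoy_feature_count):
        table[f"decoy_{k:02d}"] = decoy_rng.normal(size=n)
    return table


def true_log_odds(table: pd.DataFrame, model: TrueDecisionModel) -> np.ndarray:
    """Total true log-odds for infarction rows: intercept + effects + offset.

    Haemorrhagic rows are outside the log-odds model (their label is
    deterministically 0); calling this on them raises.
    """
    _domain_check(table)
    if len(table) and (table["infarction"] == 0).any():
        raise ValueError("true_log_odds is defined for infarction rows only")
    effects = model.feature_effects(table)
    try:
        offsets = table["stroke_team"].map(model.offsets).astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise KeyError("unknown stroke team in table") from exc
    if len(table) and np.isnan(offsets).any():
        raise KeyError("unknown stroke team in table")
    return model.intercept + effects.sum(axis=1).to_numpy() + offsets


def assign_labels(table: pd.DataFrame, model: TrueDecisionModel,
                  seed: int) -> pd.DataFrame:
    """Attach thrombolysis labels: Bernoulli(logistic(log-odds)) for infarcts,
    deterministic 0 for haemorrhage."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    out = table.copy()
    labels = np.zeros(len(table), dtype=int)
    mask = (table["infarction"] == 1).to_numpy()
    if mask.any():
        lo = true_log_odds(table.loc[mask], model)
        p = 1.0 / (1.0 + np.exp(-lo))
        labels[mask] = (rng.random(mask.sum()) < p).astype(int)
    out[LABEL_COLUMN] = labels
    return out


def generate_dataset(config: GeneratorConfig
                     ) -> tuple[pd.DataFrame, list[HospitalProfile], TrueDecisionModel]:
    """Full generation pipeline: hospitals, patients, labels.

    Returns the labelled table, the hospital profiles, and the ground-truth
    decision model. Byte-identical output for identical configs.
    """
    hospitals = sample_hospitals(config)
    model = TrueDecisionModel(
        intercept=config.intercept,
        effects=config.effect_params,
        offsets={h.team_id: h.true_offset for h in hospitals},
    )
    table = sample_patients(config, hospitals)
    return assign_labels(table, model, config.seed), hospitals, model


# -- persistence -----------------------------------------------------------

def write_dataset(table: pd.DataFrame, path,
                  hospitals: list[HospitalProfile] | None = None,
                  model: TrueDecisionModel | None = None) -> None:
    """Write the table as CSV plus a YAML ground-truth sidecar.

    The sidecar (``<path>.truth.yaml``) records hospital offsets, process
    descriptors and effect parameters so recovery analyses can be run on
    a re-loaded dataset.
    """
    validate_table(table)
    path = str(path)
    table.to_csv(path, index=False)
    if hospitals is not None or model is not None:
        truth: dict = {}
        if hospitals is not None:
            truth["hospitals"] = [asdict(h) for h in hospitals]
        if model is not None:
            truth["model"] = {
                "intercept": model.intercept,
                "effects": asdict(model.effects),
                "offsets": model.offsets,
            }
        with open(path + ".truth.yaml", "w") as fh:
            yaml.safe_dump(truth, fh, sort_keys=False)


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a dataset CSV written by :func:`write_dataset`."""
    table = pd.read_csv(path, dtype={"stroke_team": str})
    validate_table(table)
    return table


def read_truth(path) -> tuple[list[HospitalProfile], TrueDecisionModel]:
    """Load the ground-truth sidecar for a dataset CSV path."""
    with open(str(path) + ".truth.yaml") as fh:
        truth = yaml.safe_load(fh)
    hospitals = [HospitalProfile(**h) for h in truth.get("hospitals", [])]
    m = truth["model"]
    model = TrueDecisionModel(intercept=m["intercept"],
                              effects=EffectParams(**m["effects"]),
                              offsets=m["offsets"])
    return hospitals, model
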