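"""Synthetic raw-cohort generator.

Emulates the statistical structure of a mixed EHR + wearable study cohort:
a demographics table (with repeated, occasionally missing anthropometrics),
a long-format ICD-10 diagnosis table, a laboratory table with normal ranges,
and an Apple-Watch-style active-energy-burned (AEB) event stream containing
occasional device-error events longer than three hours.

Every downstream stage of the package (preprocessing, obfuscation, synthesis,
evaluation) is exercised against cohorts produced here, so no restricted data
is ever needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CohortSpec", "CohortBundle", "default_spec", "generate_cohort"]

#: ICD-10 parent letters retained after dropping the low-representation
#: categories W, U, V, Y, P and X.
ICD_LETTERS: tuple[str, ...] = tuple("ABCDEFGHIJKLMNOQRSTZ")

#: Letters excluded from analysis because of low representation.
EXCLUDED_ICD_LETTERS: frozenset[str] = frozenset("WUVYPX")

_EPOCH = pd.Timestamp("2019-01-01 00:00:00")


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Defaults (see :func:`default_spec`) reproduce the marginal summaries of
    the study's original analytical cohort: age 45.4 (16.9) y, height 169.3
    (9.9) cm, weight 83 (19.8) kg, 54.84% female, 58.4% married, 10.2%
    Hispanic, and the twenty ICD parent-letter prevalences.
    """

    n_subjects: int = 1000
    seed: int = 0
    age_mean: float = 45.4
    age_sd: float = 16.9
    height_mean: float = 169.3
    height_sd: float = 9.9
    weight_mean: float = 83.0
    weight_sd: float = 19.8
    prop_female: float = 0.5484
    prop_married: float = 0.584
    prop_hispanic: float = 0.102
    race_probs: dict[str, float] = field(default_factory=dict)
    language_probs: dict[str, float] = field(default_factory=dict)
    icd_letter_prev: dict[str, float] = field(default_factory=dict)
    latent_icd_corr: float = 0.3
    aeb_events_per_day: float = 1.0
    aeb_duration_logmean: float = 7.2   # log-seconds; median ~22 min
    aeb_duration_logsd: float = 0.8
    aeb_kcal_rate_mean: float = 300.0   # kcal per active hour
    aeb_kcal_rate_sd: float = 60.0
    kcal_weight_slope: float = 1.5      # kcal/hour per kg above the mean weight
    error_event_rate: float = 0.01     # probability an event exceeds 3 h
    only_error_subject_rate: float = 0.007  # subjects whose few events are all errors
    n_days_observed: int = 30
    lab_panel: list[tuple] = field(default_factory=list)
    missing_anthro_rate: float = 0.145
    no_wearable_rate: float = 0.342
    repeat_anthro_rate: float = 0.3
    excluded_letter_code_rate: float = 0.05

    def __post_init__(self) -> None:
        if not self.race_probs:
            # Table-1 proportions renormalized to sum to one.
            raw = {
                "Caucasian": 0.506,
                "African American": 0.183,
                "Asian": 0.193,
                "Other": 0.119,
            }
            total = sum(raw.values())
            self.race_probs = {k: v / total for k, v in raw.items()}
        if not self.language_probs:
            self.language_probs = {"English": 0.90, "Spanish": 0.06, "Other": 0.04}
        if not self.icd_letter_prev:
            self.icd_letter_prev = dict(_TABLE1_ICD_PREV)
        if not self.lab_panel:
            # (name, range_low, range_high, result_mean, result_sd, units)
            self.lab_panel = [
                ("Hemoglobin", 12.0, 16.0, 14.0, 1.6, "g/dL"),
                ("Glucose", 70.0, 100.0, 88.0, 14.0, "mg/dL"),
            ]
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        probs = [self.prop_female, self.prop_married, self.prop_hispanic,
                 self.error_event_rate, self.missing_anthro_rate,
                 self.no_wearable_rate, self.repeat_anthro_rate,
                 self.only_error_subject_rate,
                 *self.icd_letter_prev.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.race_probs.values()) - 1.0) > 1e-9:
            raise ValueError("race_probs must sum to 1")
        if not 0.0 <= self.latent_icd_corr < 1.0:
            raise ValueError("latent_icd_corr must lie in [0, 1)")
        for sd in (self.age_sd, self.height_sd, self.weight_sd,
                   self.aeb_duration_logsd, self.aeb_kcal_rate_sd):
            if sd <= 0:
                raise ValueError("all standard deviations must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        return cls(**json.loads(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        import yaml
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        import yaml
        return cls(**yaml.safe_load(Path(path).read_text()))


# Table-1 "Original" column prevalences for the twenty retained parent letters.
_TABLE1_ICD_PREV: dict[str, float] = {
    "A": 0.015, "B": 0.034, "C": 0.053, "D": 0.111, "E": 0.259,
    "F": 0.147, "G": 0.183, "H": 0.110, "I": 0.198, "J": 0.119,
    "K": 0.168, "L": 0.094, "M": 0.274, "N": 0.158, "O": 0.036,
    "Q": 0.015, "R": 0.308, "S": 0.065, "T": 0.030, "Z": 0.339,
}


@dataclass
class CohortBundle:
    """Raw multi-table cohort keyed by ``subject_id``."""

    demographics: pd.DataFrame
    icd: pd.DataFrame
    labs: pd.DataFrame
    events: pd.DataFrame

    def validate(self) -> None:
        """Check referential and temporal integrity."""
        subjects = set(self.demographics["subject_id"])
        for name in ("icd", "labs", "events"):
            tab = getattr(self, name)
            extra = set(tab["subject_id"]) - subjects
            if extra:
                raise ValueError(f"{name} table references unknown subjects: {sorted(extra)[:5]}")
        if len(self.events):
            if not (self.events["end"] > self.events["start"]).all():
                raise ValueError("every event must satisfy end > start")
            if not (self.events["kcal"] >= 0).all():
                raise ValueError("kcal must be non-negative")

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("demographics", "icd", "labs", "events"):
            getattr(self, name).to_csv(directory / f"{name}.csv", index=False)

    @classmethod
    def from_csv(cls, directory: str | Path) -> "CohortBundle":
        directory = Path(directory)
        tables = {}
        for name in ("demographics", "icd", "labs", "events"):
            kwargs = {"parse_dates": ["start", "end"]} if name == "events" else {}
            tables[name] = pd.read_csv(directory / f"{name}.csv", **kwargs)
        return cls(**tables)


def default_spec(**overrides) -> CohortSpec:
    """Cohort spec whose parameters equal the study's original-cohort summaries."""
    return CohortSpec(**overrides)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               low: float, high: float, size: int) -> np.ndarray:
    """Truncated-normal draws whose *truncated* mean/SD equal the targets.

    The underlying location/scale are solved so that truncation (e.g. age
    >= 18) does not shift the observed moments away from the cohort
    summaries the spec encodes.
    """
    from scipy.optimize import root

    def moments(params):
        loc, log_scale = params
        scale = np.exp(log_scale)
        a, b = (low - loc) / scale, (high - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = root(moments, x0=[mean, np.log(sd)], tol=1e-10)
    loc, scale = sol.x[0], float(np.exp(sol.x[1]))
    a, b = (low - loc) / scale, (high - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def _empty_bundle() -> CohortBundle:
    demo_cols = ["subject_id", "age", "gender", "marital", "race", "ethnicity",
                 "language", "height_cm", "weight_kg"]
    return CohortBundle(
        demographics=pd.DataFrame(columns=demo_cols),
        icd=pd.DataFrame(columns=["subject_id", "icd_code"]),
        labs=pd.DataFrame(columns=["subject_id", "lab_name", "result", "units",
                                   "range_low", "range_high"]),
        events=pd.DataFrame(columns=["subject_id", "start", "end", "kcal"]),
    )


def generate_cohort(spec: CohortSpec) -> CohortBundle:
    """Draw a raw cohort from ``spec``.

    Deterministic given ``spec.seed``.  ICD letter flags share a single
    standard-normal latent factor per subject (probit model), so letters
    co-occur positively when ``latent_icd_corr > 0``.  A fraction
    ``no_wearable_rate`` of subjects has zero wearable events, a fraction
    ``missing_anthro_rate`` lacks height/weight, and a fraction
    ``error_event_rate`` of events lasts longer than three hours
    (emulating device recording errors).
    """
    spec.validate()
    n = spec.n_subjects
    if n == 0:
        return _empty_bundle()

    rng = np.random.default_rng(spec.seed)
    sid = np.array([f"S{i:06d}" for i in range(n)])

    age = np.round(_truncnorm(rng, spec.age_mean, spec.age_sd, 18.0, 100.0, n), 1)
    height = np.round(_truncnorm(rng, spec.height_mean, spec.height_sd, 120.0, 220.0, n), 1)
    weight = np.round(_truncnorm(rng, spec.weight_mean, spec.weight_sd, 30.0, 250.0, n), 1)
    gender = np.where(rng.random(n) < spec.prop_female, "Female", "Male")
    marital = np.where(rng.random(n) < spec.prop_married, "Married", "Single")
    races = list(spec.race_probs)
    race = rng.choice(races, size=n, p=[spec.race_probs[r] for r in races])
    ethnicity = np.where(rng.random(n) < spec.prop_hispanic,
                         "Hispanic or Latino", "Not Hispanic or Latino")
    langs = list(spec.language_probs)
    language = rng.choice(langs, size=n, p=[spec.language_probs[la] for la in langs])

    missing_anthro = rng.random(n) < spec.missing_anthro_rate
    no_wearable = rng.random(n) < spec.no_wearable_rate

    # Demographics rows; ~repeat_anthro_rate of subjects get a second
    # anthropometric measurement with small re-measurement noise.
    demo = pd.DataFrame({
        "subject_id": sid, "age": age, "gender": gender, "marital": marital,
        "race": race, "ethnicity": ethnicity, "language": language,
        "height_cm": np.where(missing_anthro, np.nan, height),
        "weight_kg": np.where(missing_anthro, np.nan, weight),
    })
    repeat = (rng.random(n) < spec.repeat_anthro_rate) & ~missing_anthro
    if repeat.any():
        dup = demo.loc[repeat].copy()
        m = int(repeat.sum())
        dup["height_cm"] = np.round(dup["height_cm"] + rng.normal(0, 0.5, m), 1)
        dup["weight_kg"] = np.round(np.maximum(dup["weight_kg"] + rng.normal(0, 1.0, m), 30.0), 1)
        demo = pd.concat([demo, dup], ignore_index=True)
        demo = demo.sort_values("subject_id", kind="stable").reset_index(drop=True)

    # ICD flags: probit with one shared latent factor per subject.
    rho = spec.latent_icd_corr
    factor = rng.standard_normal(n)
    letters = [let for let in ICD_LETTERS if let in spec.icd_letter_prev]
    icd_rows: list[tuple[str, str]] = []
    for let in letters:
        p = spec.icd_letter_prev[let]
        if p <= 0:
            continue
        z = np.sqrt(rho) * factor + np.sqrt(1 - rho) * rng.standard_normal(n)
        flags = z < stats.norm.ppf(p)
        for i in np.nonzero(flags)[0]:
            code = f"{let}{rng.integers(10, 100)}.{rng.integers(0, 10)}"
            icd_rows.append((sid[i], code))
    # A few codes from the excluded letters so preprocessing has something to drop.
    excl = rng.random(n) < spec.excluded_letter_code_rate
    for i in np.nonzero(excl)[0]:
        let = rng.choice(list("WUVYPX"))
        icd_rows.append((sid[i], f"{let}{rng.integers(10, 100)}"))
    icd = pd.DataFrame(icd_rows, columns=["subject_id", "icd_code"])

    # Labs: results normal around mid-range, ~10% drawn outside the range.
    lab_rows = []
    for name, low, high, mu, sd_lab, units in spec.lab_panel:
        res = rng.normal(mu, sd_lab, n)
        outside = rng.random(n) < 0.10
        width = high - low
        res[outside] = np.where(rng.random(int(outside.sum())) < 0.5,
                                low - rng.uniform(0.05, 0.5, int(outside.sum())) * width,
                                high + rng.uniform(0.05, 0.5, int(outside.sum())) * width)
        for i in range(n):
            lab_rows.append((sid[i], name, round(float(res[i]), 2), units, low, high))
    labs = pd.DataFrame(lab_rows, columns=["subject_id", "lab_name", "result",
                                           "units", "range_low", "range_high"])

    # AEB events on a synthetic calendar starting at an arbitrary epoch.
    kcal_rate = (spec.aeb_kcal_rate_mean
                 + spec.kcal_weight_slope * (weight - spec.weight_mean)
                 + rng.normal(0, spec.aeb_kcal_rate_sd, n))
    kcal_rate = np.maximum(kcal_rate, 10.0)
    only_error = rng.random(n) < spec.only_error_subject_rate
    ev_rows = []
    for i in range(n):
        if no_wearable[i]:
            continue
        if only_error[i]:
            n_ev = int(rng.integers(1, 4))
        else:
            n_ev = rng.poisson(spec.aeb_events_per_day * spec.n_days_observed)
        if n_ev == 0:
            continue
        day = rng.integers(0, spec.n_days_observed, n_ev)
        start_s = day * 86400 + rng.uniform(6 * 3600, 20 * 3600, n_ev)
        dur = rng.lognormal(spec.aeb_duration_logmean, spec.aeb_duration_logsd, n_ev)
        dur = np.minimum(dur, 10800.0 - 1.0)  # regular events stay under 3 h
        err = (rng.random(n_ev) < spec.error_event_rate) | only_error[i]
        dur[err] = rng.uniform(10801.0, 8 * 3600.0, int(err.sum()))
        kcal = dur / 3600.0 * kcal_rate[i] * rng.lognormal(0, 0.05, n_ev)
        for j in range(n_ev):
            ev_rows.append((sid[i],
                            _EPOCH + pd.Timedelta(seconds=round(float(start_s[j]))),
                            _EPOCH + pd.Timedelta(seconds=round(float(start_s[j] + dur[j]))),
                            round(float(kcal[j]), 2)))
    events = pd.DataFrame(ev_rows, columns=["subject_id", "start", "end", "kcal"])
    if len(events) == 0:
        events = _empty_bundle().events

    bundle = CohortBundle(demographics=demo, icd=icd, labs=labs, events=events)
    bundle.validate()
    return bundle
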