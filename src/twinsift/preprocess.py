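"""Raw cohort -> one-row-per-subject analytical table.

The pipeline mirrors a standard EHR feature-engineering pass for this kind of
wearable study:

* ICD-10 codes are grouped to their parent letter (``"I25.10" -> "I"``),
  dropping the low-representation categories W, U, V, Y, P, X; patient-level
  letter combinations seen in exactly one patient are consolidated into the
  closest overlapping non-singleton combination; the surviving combinations
  are binarized across the twenty retained letters.
* Laboratory results are flagged high/low/normal against the reported range
  and summarized per subject as H/L counts per lab.
* Anthropometrics are averaged per subject; BMI is derived from the means.
* Active-energy-burned (AEB) events longer than three hours are removed as
  device recording errors; per-subject totals yield the daily-normalized
  outcome ``avg_aeb_day = sum_aeb / (sum_seconds / 86400)``.

Exclusions (no wearable data; missing height/weight; only >3 h events) are
applied in that order and tallied in an :class:`AttritionReport`.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fixtures import CohortBundle, ICD_LETTERS, EXCLUDED_ICD_LETTERS

__all__ = [
    "AttritionReport", "IcdCombination", "ConsolidationResult",
    "icd_to_letter", "consolidate_singletons", "flag_lab", "filter_events",
    "apply_exclusions", "compute_aeb_outcome", "build_analytical",
]

MAX_EVENT_SECONDS = 3 * 3600  # events strictly longer than this are errors

ICD_FLAG_COLUMNS = [f"icd_{let}" for let in ICD_LETTERS]

DEMOGRAPHIC_CATEGORICALS = ["gender", "marital", "race", "ethnicity", "language"]


@dataclass
class AttritionReport:
    """Counts removed by each exclusion rule; always reconciles to n_final."""

    n_start: int
    n_excluded_no_wearable: int
    n_excluded_missing_anthro: int
    n_excluded_only_long_events: int
    n_final: int

    def __post_init__(self) -> None:
        removed = (self.n_excluded_no_wearable + self.n_excluded_missing_anthro
                   + self.n_excluded_only_long_events)
        if self.n_final != self.n_start - removed:
            raise ValueError("attrition counts do not reconcile")
        if min(asdict(self).values()) < 0:
            raise ValueError("attrition counts must be non-negative")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


@dataclass(frozen=True)
class IcdCombination:
    """A patient-level set of ICD parent letters and its cohort frequency."""

    letters: frozenset[str]
    frequency: int

    def __post_init__(self) -> None:
        if not self.letters:
            raise ValueError("letters must be nonempty")
        if not self.letters <= set(ICD_LETTERS):
            raise ValueError("letters must be among the 20 retained parent letters")


@dataclass
class ConsolidationResult:
    """Mapping from each combination to its consolidated target.

    ``flagged`` holds singletons with no overlapping non-singleton partner;
    they map to themselves and drive the ``oth_icd`` indicator.
    """

    mapping: dict[frozenset, frozenset]
    flagged: set[frozenset] = field(default_factory=set)


def icd_to_letter(code: str) -> str | None:
    """Parent letter of an ICD-10 code, or ``None`` for excluded categories.

    >>> icd_to_letter("I25.10")
    'I'
    """
    if not code or not str(code).strip():
        raise ValueError("ICD code must be nonempty")
    first = str(code).strip()[0].upper()
    if not first.isalpha():
        raise ValueError(f"ICD code must start with a letter: {code!r}")
    if first in EXCLUDED_ICD_LETTERS:
        return None
    return first


def consolidate_singletons(combos: list[IcdCombination]) -> ConsolidationResult:
    """Fold frequency-1 letter combinations into the closest non-singleton.

    Closeness is Jaccard similarity of the letter sets; ties are broken by
    higher candidate frequency, then by the lexicographic order of the sorted
    letter string.  A singleton with no overlapping non-singleton candidate
    maps to itself and is flagged.
    """
    for c in combos:
        if c.frequency < 1:
            raise ValueError("frequencies must be >= 1")
    mapping: dict[frozenset, frozenset] = {}
    flagged: set[frozenset] = set()
    non_single = [c for c in combos if c.frequency >= 2]
    for c in combos:
        if c.frequency >= 2:
            mapping[c.letters] = c.letters
            continue
        best = None
        for cand in non_single:
            inter = len(c.letters & cand.letters)
            if inter == 0:
                continue
            jac = inter / len(c.letters | cand.letters)
            key = (jac, cand.frequency, "".join(sorted(cand.letters)))
            # lexicographically *smaller* string wins a full tie, so invert
            if best is None or (key[0], key[1]) > (best[0], best[1]) or (
                    key[:2] == best[:2] and key[2] < best[2]):
                best = key
                mapping[c.letters] = cand.letters
        if c.letters not in mapping:
            mapping[c.letters] = c.letters
            flagged.add(c.letters)
    return ConsolidationResult(mapping=mapping, flagged=flagged)


def flag_lab(result: float, low: float, high: float) -> str:
    """Classify a lab result as ``"L"``, ``"N"`` or ``"H"`` (boundaries are N)."""
    if pd.isna(low) or pd.isna(high):
        raise ValueError("missing normal range; record is unevaluable")
    if low > high:
        raise ValueError("range_low must not exceed range_high")
    if result < low:
        return "L"
    if result > high:
        return "H"
    return "N"


def filter_events(events: pd.DataFrame) -> pd.DataFrame:
    """Drop AEB events strictly longer than three hours (device errors)."""
    if len(events) == 0:
        return events.copy()
    dur = (events["end"] - events["start"]).dt.total_seconds()
    return events.loc[dur <= MAX_EVENT_SECONDS].reset_index(drop=True)


def apply_exclusions(bundle: CohortBundle) -> tuple[CohortBundle, AttritionReport]:
    """Apply the three exclusion rules in order and tally attrition.

    1. no wearable data (zero AEB events);
    2. missing weight and/or height (no non-missing value in any row);
    3. only AEB events lasting > 3 h (nothing left after error filtering).

    The returned bundle's event table is error-filtered.
    """
    demo = bundle.demographics
    subjects = pd.unique(demo["subject_id"])
    n_start = len(subjects)

    has_events = set(bundle.events["subject_id"]) if len(bundle.events) else set()
    no_wearable = [s for s in subjects if s not in has_events]
    kept = [s for s in subjects if s in has_events]

    anthro = demo.groupby("subject_id")[["height_cm", "weight_kg"]].mean()
    missing = {s for s in kept
               if s not in anthro.index
               or pd.isna(anthro.loc[s, "height_cm"])
               or pd.isna(anthro.loc[s, "weight_kg"])}
    kept2 = [s for s in kept if s not in missing]

    filtered_events = filter_events(bundle.events)
    still_has = set(filtered_events["subject_id"]) if len(filtered_events) else set()
    only_long = [s for s in kept2 if s not in still_has]
    final = [s for s in kept2 if s in still_has]

    report = AttritionReport(
        n_start=n_start,
        n_excluded_no_wearable=len(no_wearable),
        n_excluded_missing_anthro=len(missing),
        n_excluded_only_long_events=len(only_long),
        n_final=len(final),
    )
    keep = set(final)
    out = CohortBundle(
        demographics=demo[demo["subject_id"].isin(keep)].reset_index(drop=True),
        icd=bundle.icd[bundle.icd["subject_id"].isin(keep)].reset_index(drop=True),
        labs=bundle.labs[bundle.labs["subject_id"].isin(keep)].reset_index(drop=True),
        events=filtered_events[filtered_events["subject_id"].isin(keep)].reset_index(drop=True),
    )
    return out, report


def compute_aeb_outcome(events: pd.DataFrame) -> tuple[float, float, float]:
    """Per-subject AEB totals and the daily-normalized outcome.

    Returns ``(sum_aeb, sum_seconds, avg_aeb_day)`` where
    ``avg_aeb_day = sum_aeb / (sum_seconds / 86400)``.
    """
    if len(events) == 0:
        raise ValueError("subject has no events; should have been excluded upstream")
    sum_aeb = float(events["kcal"].sum())
    sum_seconds = float((events["end"] - events["start"]).dt.total_seconds().sum())
    return sum_aeb, sum_seconds, sum_aeb / (sum_seconds / 86400.0)


def _lab_col(name: str, flag: str) -> str:
    return f"lab_{re.sub(r'[^a-z0-9]+', '_', name.lower())}_{flag}"


def build_analytical(bundle: CohortBundle, include_labs: bool = True) -> pd.DataFrame:
    """Assemble the one-row-per-subject analytical table.

    The bundle must already be exclusion-filtered (see
    :func:`apply_exclusions`).  Raises if a subject carries conflicting
    categorical demographics across rows.
    """
    demo = bundle.demographics
    for col in DEMOGRAPHIC_CATEGORICALS + ["age"]:
        n_distinct = demo.groupby("subject_id")[col].nunique(dropna=False)
        bad = n_distinct[n_distinct > 1]
        if len(bad):
            raise ValueError(f"conflicting {col!r} values for subjects {list(bad.index)[:5]}")

    first = demo.groupby("subject_id").first()
    anthro = demo.groupby("subject_id")[["height_cm", "weight_kg"]].mean()
    table = first[["age"] + DEMOGRAPHIC_CATEGORICALS].copy()
    table["height_cm"] = anthro["height_cm"]
    table["weight_kg"] = anthro["weight_kg"]
    table["bmi"] = table["weight_kg"] / (table["height_cm"] / 100.0) ** 2

    # ICD letters -> per-subject combinations -> singleton consolidation -> flags
    letters_by_subject: dict[str, frozenset] = {}
    if len(bundle.icd):
        lets = bundle.icd["icd_code"].map(icd_to_letter)
        valid = bundle.icd.loc[lets.notna()].assign(letter=lets[lets.notna()])
        grp = valid.groupby("subject_id")["letter"].agg(lambda s: frozenset(s))
        letters_by_subject = {s: fs for s, fs in grp.items() if fs}
    combo_freq: dict[frozenset, int] = {}
    for fs in letters_by_subject.values():
        combo_freq[fs] = combo_freq.get(fs, 0) + 1
    combos = [IcdCombination(letters=k, frequency=v) for k, v in combo_freq.items()]
    cons = consolidate_singletons(combos)

    flags = pd.DataFrame(0, index=table.index, columns=ICD_FLAG_COLUMNS, dtype=int)
    oth = pd.Series(0, index=table.index, dtype=int)
    for s, fs in letters_by_subject.items():
        if s not in table.index:
            continue
        target = cons.mapping.get(fs, fs)
        for let in target:
            flags.loc[s, f"icd_{let}"] = 1
        if fs in cons.flagged:
            oth.loc[s] = 1
    table = table.join(flags)
    table["any_icd"] = (flags.sum(axis=1) > 0).astype(int)
    table["oth_icd"] = oth

    if include_labs and len(bundle.labs):
        lab = bundle.labs.copy()
        evaluable = lab["range_low"].notna() & lab["range_high"].notna()
        if (~evaluable).any():
            warnings.warn(f"{int((~evaluable).sum())} lab records lack a normal "
                          "range and were excluded from lab features")
        lab = lab.loc[evaluable]
        lab["flag"] = [flag_lab(r, lo, hi) for r, lo, hi in
                       zip(lab["result"], lab["range_low"], lab["range_high"])]
        for name in sorted(lab["lab_name"].unique()):
            sub = lab[lab["lab_name"] == name]
            for fl in ("H", "L"):
                counts = sub[sub["flag"] == fl].groupby("subject_id").size()
                table[_lab_col(name, fl)] = counts.reindex(table.index, fill_value=0).astype(int)

    # AEB outcome from the (already error-filtered) event stream
    ev = bundle.events
    dur = (ev["end"] - ev["start"]).dt.total_seconds()
    agg = ev.assign(dur=dur).groupby("subject_id").agg(
        sum_aeb=("kcal", "sum"), sum_seconds=("dur", "sum"))
    missing_ev = set(table.index) - set(agg.index)
    if missing_ev:
        raise ValueError(f"subjects without events in exclusion-filtered bundle: "
                         f"{sorted(missing_ev)[:5]}")
    table["sum_aeb"] = agg["sum_aeb"]
    table["sum_seconds"] = agg["sum_seconds"]
    table["avg_aeb_day"] = table["sum_aeb"] / (table["sum_seconds"] / 86400.0)

    return table.reset_index().rename(columns={"index": "subject_id"})
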