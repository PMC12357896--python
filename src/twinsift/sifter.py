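"""Titratable statistical obfuscation of the analytical table and event stream.

Cross-sectional obfuscation ("sifting") runs repeated cycles of artificial
missingness followed by model-based imputation, then exchanges values between
nearest-neighbour cases under a Gower-style mixed-type distance.  Four
controls titrate the privacy/utility trade-off:

1. ``miss_prop``   — proportion of cells per targeted feature blanked per cycle;
2. ``n_cycles``    — number of paired missingness/imputation iterations;
3. ``feature_prop``— proportion of obfuscatable features targeted;
4. ``swap_prop``   — proportion of cases swapped with one of their
   ``k_neighbors`` closest neighbours.

Three presets (small / medium / large) bundle these controls.  Imputation
uses per-column decision trees with leaf-donor sampling: a masked cell is
filled with the observed value of a randomly drawn training row from the same
leaf, so imputed values always lie on the observed marginal.

The longitudinal obfuscator perturbs the wearable event stream directly:
whole-day event blocks are exchanged between subjects that are adjacent under
a daily-energy-profile distance, event start times are jittered within their
calendar day, and kcal values receive multiplicative log-normal noise.  Event
count and (for the first two mechanisms) per-event durations are preserved.

Derived columns — BMI, ``any_icd`` and the AEB aggregates — are never sifted
directly; they are recomputed from their obfuscated components afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "SifterParams", "DsloParams", "TwinTable", "preset", "dslo_preset",
    "inject_missingness", "impute", "swap_neighbors", "sift", "dslo",
    "NON_OBFUSCATABLE",
]

#: Columns never sifted directly: identifiers and fully dependent/derived
#: columns that are recomputed after obfuscation.
NON_OBFUSCATABLE = ("subject_id", "bmi", "avg_aeb_day", "sum_aeb",
                    "sum_seconds", "any_icd")


@dataclass
class SifterParams:
    """The four titratable sifting controls plus a level label and seed."""

    level: str = "custom"
    miss_prop: float = 0.0
    n_cycles: int = 0
    feature_prop: float = 0.0
    swap_prop: float = 0.0
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("miss_prop", "feature_prop", "swap_prop"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")

    def to_yaml(self, path) -> None:
        import yaml
        from pathlib import Path
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SifterParams":
        import yaml
        from pathlib import Path
        return cls(**yaml.safe_load(Path(path).read_text()))


_PRESETS: dict[str, dict] = {
    "small": dict(miss_prop=0.05, n_cycles=1, feature_prop=0.25,
                  swap_prop=0.05, k_neighbors=5),
    "medium": dict(miss_prop=0.15, n_cycles=2, feature_prop=0.50,
                   swap_prop=0.20, k_neighbors=5),
    "large": dict(miss_prop=0.30, n_cycles=3, feature_prop=1.00,
                  swap_prop=0.40, k_neighbors=3),
}


def preset(level: str, seed: int = 0) -> SifterParams:
    """Fixed parameter bundle for an obfuscation level (small/medium/large)."""
    if level not in _PRESETS:
        raise ValueError(f"unknown obfuscation level {level!r}; "
                         f"expected one of {sorted(_PRESETS)}")
    return SifterParams(level=level, seed=seed, **_PRESETS[level])


@dataclass
class TwinTable:
    """An obfuscated/synthetic table plus provenance."""

    data: pd.DataFrame
    method: str
    level: str
    seed: int
    params: dict = field(default_factory=dict)

    def provenance(self) -> dict:
        return {"method": self.method, "level": self.level,
                "seed": self.seed, "params": self.params}


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _is_numeric(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s)


def inject_missingness(table: pd.DataFrame, params: SifterParams,
                       columns: list[str] | None = None,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank ``round(miss_prop * n_rows)`` cells per targeted column.

    Returns the blanked table and a boolean mask of blanked positions.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    columns = list(columns) if columns is not None else list(table.columns)
    out = table.copy()
    mask = pd.DataFrame(False, index=table.index, columns=table.columns)
    n_blank = _round_half_up(params.miss_prop * len(table))
    for col in columns:
        idx = rng.choice(len(table), size=n_blank, replace=False)
        rows = table.index[idx]
        out.loc[rows, col] = np.nan
        mask.loc[rows, col] = True
    return out, mask


def _encode_predictors(table: pd.DataFrame, exclude: str) -> np.ndarray:
    """Ordinal-encode all columns except ``exclude``; NaNs -> column median."""
    cols = []
    for col in table.columns:
        if col == exclude:
            continue
        s = table[col]
        if not _is_numeric(s):
            codes, _ = pd.factorize(s, use_na_sentinel=True)
            s = pd.Series(codes, index=s.index, dtype=float).replace(-1, np.nan)
        else:
            s = s.astype(float)
        med = s.median()
        cols.append(s.fillna(0.0 if pd.isna(med) else med).to_numpy())
    if not cols:
        return np.zeros((len(table), 1))
    return np.column_stack(cols)


def impute(table: pd.DataFrame, mask: pd.DataFrame,
           rng: np.random.Generator | None = None,
           id_columns: tuple[str, ...] = ("subject_id",)) -> pd.DataFrame:
    """Fill masked cells by leaf-donor sampling from per-column decision trees.

    For each masked column a regression tree is grown on the observed rows
    (categoricals handled through ordinal target coding), and each masked
    cell receives the *observed* value of a random training row in the same
    leaf.  Unmasked cells are never touched.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    out = table.copy()
    masked_cols = [c for c in table.columns if mask[c].any() and c not in id_columns]
    for col in sorted(masked_cols):
        obs = ~mask[col]
        if not obs.any():
            raise ValueError(f"column {col!r} entirely blank; cannot impute")
        predictors = out.drop(columns=[c for c in id_columns if c in out.columns])
        X = _encode_predictors(predictors, exclude=col)
        X_obs, X_mis = X[obs.to_numpy()], X[mask[col].to_numpy()]
        y_obs = table.loc[obs, col]
        if _is_numeric(y_obs):
            y_fit = y_obs.astype(float).to_numpy()
        else:
            y_fit, _ = pd.factorize(y_obs)
            y_fit = y_fit.astype(float)
        tree = DecisionTreeRegressor(max_depth=12, min_samples_leaf=5,
                                     random_state=int(rng.integers(2**31)))
        tree.fit(X_obs, y_fit)
        leaves_obs = tree.apply(X_obs)
        leaves_mis = tree.apply(X_mis)
        donors_by_leaf: dict[int, np.ndarray] = {}
        obs_values = y_obs.to_numpy()
        for leaf in np.unique(leaves_obs):
            donors_by_leaf[leaf] = np.nonzero(leaves_obs == leaf)[0]
        fill = []
        for leaf in leaves_mis:
            pool = donors_by_leaf[leaf]
            fill.append(obs_values[pool[rng.integers(len(pool))]])
        out.loc[mask[col], col] = fill
        if (pd.api.types.is_integer_dtype(table[col].dtype)
                and not out[col].isna().any()):
            out[col] = out[col].astype(table[col].dtype)
    return out


def _gower_to_all(table: pd.DataFrame, row: int, numeric: list[str],
                  ranges: dict[str, float]) -> np.ndarray:
    """Gower distance from one row to every row (range-normalized numeric,
    0/1 mismatch categorical, averaged over features)."""
    n = len(table)
    acc = np.zeros(n)
    p = 0
    for col in table.columns:
        s = table[col]
        if col in numeric:
            r = ranges[col]
            d = np.abs(s.to_numpy(dtype=float) - float(s.iloc[row]))
            acc += d / r if r > 0 else 0.0
        else:
            acc += (s.to_numpy() != s.iloc[row]).astype(float)
        p += 1
    return acc / max(p, 1)


def swap_neighbors(table: pd.DataFrame, params: SifterParams,
                   columns: list[str] | None = None,
                   distance_columns: list[str] | None = None,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Exchange targeted feature values between near-neighbour cases.

    ``round(swap_prop * n_rows)`` rows are chosen without replacement; each
    exchanges its targeted values with one of its ``k_neighbors`` nearest
    rows under the Gower mixed-type distance.  Exchanges are symmetric, so
    per-column value multisets are preserved.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    if len(table) < 2:
        warnings.warn("fewer than 2 rows; swapping skipped")
        return table.copy()
    if params.k_neighbors >= len(table):
        raise ValueError("k_neighbors must be smaller than the number of rows")
    columns = list(columns) if columns is not None else list(table.columns)
    dist_cols = (list(distance_columns) if distance_columns is not None
                 else columns)
    out = table.reset_index(drop=True)
    dist_tab = out[dist_cols]
    numeric = [c for c in dist_cols if _is_numeric(dist_tab[c])]
    ranges = {c: float(dist_tab[c].max() - dist_tab[c].min()) for c in numeric}

    n_swap = _round_half_up(params.swap_prop * len(out))
    chosen = rng.choice(len(out), size=n_swap, replace=False)
    result = out.copy()
    for i in chosen:
        d = _gower_to_all(dist_tab, int(i), numeric, ranges)
        d[i] = np.inf
        nearest = np.argpartition(d, params.k_neighbors)[:params.k_neighbors]
        j = int(nearest[rng.integers(len(nearest))])
        for col in columns:
            vi, vj = result.at[i, col], result.at[j, col]
            result.at[i, col], result.at[j, col] = vj, vi
    result.index = table.index
    return result


def _recompute_derived(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute fully dependent columns from their (possibly sifted) parts."""
    out = table.copy()
    if {"height_cm", "weight_kg", "bmi"} <= set(out.columns):
        out["bmi"] = out["weight_kg"].astype(float) / (
            out["height_cm"].astype(float) / 100.0) ** 2
    flag_cols = [c for c in out.columns if c.startswith("icd_")]
    if flag_cols and "any_icd" in out.columns:
        out["any_icd"] = (out[flag_cols].sum(axis=1) > 0).astype(int)
    if {"sum_aeb", "sum_seconds", "avg_aeb_day"} <= set(out.columns):
        sec = out["sum_seconds"].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out["avg_aeb_day"] = np.where(
                sec > 0, out["sum_aeb"].astype(float) / (sec / 86400.0), 0.0)
    return out


def sift(table: pd.DataFrame, params: SifterParams) -> TwinTable:
    """Full cross-sectional obfuscation pass.

    Targets ``round(feature_prop * n_obfuscatable)`` features, runs
    ``n_cycles`` of missingness+imputation, swaps neighbour values, then
    recomputes derived columns.  Deterministic given (table, params).
    """
    rng = np.random.default_rng(params.seed)
    obfuscatable = [c for c in table.columns if c not in NON_OBFUSCATABLE]
    n_target = _round_half_up(params.feature_prop * len(obfuscatable))
    targeted = sorted(rng.choice(obfuscatable, size=n_target, replace=False))

    work = table.copy()
    if targeted:
        for _ in range(params.n_cycles):
            work, mask = inject_missingness(work, params, columns=targeted, rng=rng)
            work = impute(work, mask, rng=rng)
        if params.swap_prop > 0 and len(work) >= 2:
            work = swap_neighbors(work, params, columns=targeted,
                                  distance_columns=obfuscatable, rng=rng)
    work = _recompute_derived(work)
    return TwinTable(data=work, method="datasifter", level=params.level,
                     seed=params.seed, params=asdict(params))


# ---------------------------------------------------------------------------
# Longitudinal obfuscation (wearable event stream)
# ---------------------------------------------------------------------------

@dataclass
class DsloParams:
    """Intensities of the three longitudinal mechanisms."""

    level: str = "custom"
    day_swap_frac: float = 0.0    # fraction of subject-day blocks exchanged
    jitter_seconds: float = 0.0   # max |start-time shift| within the day
    kcal_sigma: float = 0.0       # log-normal sigma of multiplicative kcal noise
    k_neighbors: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.day_swap_frac <= 1.0:
            raise ValueError("day_swap_frac must lie in [0, 1]")
        if self.jitter_seconds < 0 or self.kcal_sigma < 0:
            raise ValueError("jitter_seconds and kcal_sigma must be >= 0")


_DSLO_PRESETS: dict[str, dict] = {
    "small": dict(day_swap_frac=0.05, jitter_seconds=1800.0, kcal_sigma=0.05),
    "medium": dict(day_swap_frac=0.20, jitter_seconds=7200.0, kcal_sigma=0.15),
    "large": dict(day_swap_frac=0.40, jitter_seconds=14400.0, kcal_sigma=0.30),
}


def dslo_preset(level: str) -> DsloParams:
    if level not in _DSLO_PRESETS:
        raise ValueError(f"unknown obfuscation level {level!r}")
    return DsloParams(level=level, **_DSLO_PRESETS[level])


def dslo(events: pd.DataFrame, level: str | DsloParams, seed: int = 0) -> pd.DataFrame:
    """Longitudinal obfuscation of the AEB event stream.

    Mechanisms: (a) whole-day event blocks exchanged between subjects
    adjacent under a daily-total-AEB profile distance; (b) start-time jitter
    within the calendar day; (c) multiplicative log-normal kcal noise.
    Schema and total event count are preserved; per-event durations are
    unchanged by (a) and (b).
    """
    params = level if isinstance(level, DsloParams) else dslo_preset(level)
    rng = np.random.default_rng(seed)
    out = events.copy().reset_index(drop=True)
    if len(out) == 0:
        return out

    day = out["start"].dt.normalize()
    subjects = pd.unique(out["subject_id"])

    # (a) day-block exchange between profile neighbours
    if params.day_swap_frac > 0:
        if len(subjects) < 2:
            warnings.warn("single subject; day-block exchange disabled")
        else:
            daily = (out.assign(day=day).groupby(["subject_id", "day"])["kcal"]
                     .sum().unstack(fill_value=0.0))
            daily = daily.reindex(subjects)
            profile = daily.to_numpy(dtype=float)
            dmat = cdist(profile, profile)
            np.fill_diagonal(dmat, np.inf)
            k = min(params.k_neighbors, len(subjects) - 1)
            neighbor_idx = np.argpartition(dmat, k - 1, axis=1)[:, :k]
            subj_pos = {s: i for i, s in enumerate(subjects)}

            blocks = sorted(set(zip(out["subject_id"], day)),
                            key=lambda b: (b[0], b[1]))
            n_swap = _round_half_up(params.day_swap_frac * len(blocks))
            pick = rng.choice(len(blocks), size=n_swap, replace=False)
            sid_arr = out["subject_id"].to_numpy(dtype=object)
            day_arr = day.to_numpy()
            for b in pick:
                s_i, d = blocks[b]
                cand = neighbor_idx[subj_pos[s_i]]
                s_j = subjects[cand[rng.integers(len(cand))]]
                mask_i = (sid_arr == s_i) & (day_arr == d)
                mask_j = (sid_arr == s_j) & (day_arr == d)
                sid_arr[mask_i] = s_j
                sid_arr[mask_j] = s_i
            out["subject_id"] = sid_arr

    # (b) start-time jitter within the calendar day (durations unchanged)
    if params.jitter_seconds > 0:
        dur = out["end"] - out["start"]
        day0 = out["start"].dt.normalize()
        shift = pd.to_timedelta(
            rng.uniform(-params.jitter_seconds, params.jitter_seconds, len(out)),
            unit="s")
        new_start = out["start"] + shift
        lo = day0
        hi = day0 + pd.Timedelta(days=1) - dur
        new_start = new_start.clip(lower=lo, upper=hi.where(hi > lo, other=lo))
        out["start"] = new_start
        out["end"] = new_start + dur

    # (c) multiplicative kcal noise
    if params.kcal_sigma > 0:
        out["kcal"] = out["kcal"] * rng.lognormal(0.0, params.kcal_sigma, len(out))

    return out
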