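"""Privacy and utility evaluation battery for digital-twin tables.

Implements the full score catalogue used to benchmark an obfuscated or
synthetic table against its original:

* **Quality** — per-column shape fidelity (KS complement for numeric, total
  variation complement for categorical) and pairwise trend preservation
  (Pearson-correlation similarity, or joint-contingency similarity with
  numeric columns quantile-binned), averaged into an overall quality score.
* **Diagnostic** — per-column validity (boundary/category adherence) and
  table-structure congruence.
* **Privacy** — new-row synthesis, classifier-based detection (logistic and
  SVC), table structure, and CAP-style / regression-based inference-attack
  scores against sensitive columns.
* **ML efficacy** — train-on-synthetic / test-on-real performance, aggregated
  by target type (binary: four classifiers; multiclass: two; numeric: one).

All scores live in [0, 1]; for privacy metrics 1 means best protected, for
utility/quality metrics 1 means highest fidelity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import AdaBoostClassifier
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score, r2_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "QualityReport", "DiagnosticReport", "PrivacyReport", "UtilityReport",
    "ks_complement", "tv_complement", "pair_trend", "quality_report",
    "diagnostic_report", "table_structure", "new_row_synthesis",
    "detection_score", "inference_privacy_categorical",
    "inference_privacy_numeric", "ml_efficacy", "utility_report",
    "privacy_report", "overall_privacy", "column_types",
]

N_QUANTILE_BINS = 10          # discretization for mixed-type pair trends
NEW_ROW_NUMERIC_TOL = 0.01    # fraction of column range


def column_types(table: pd.DataFrame,
                 categorical: list[str] | None = None) -> dict[str, str]:
    """Infer per-column kind: explicit list wins, else dtype-based."""
    cats = set(categorical or [])
    out = {}
    for col in table.columns:
        if col in cats or not pd.api.types.is_numeric_dtype(table[col]):
            out[col] = "categorical"
        else:
            out[col] = "numeric"
    return out


# ---------------------------------------------------------------------------
# Column shapes
# ---------------------------------------------------------------------------

def ks_complement(real: pd.Series, synthetic: pd.Series) -> float:
    """1 minus the Kolmogorov–Smirnov sup-distance between the two ECDFs."""
    r = pd.Series(real).dropna()
    s = pd.Series(synthetic).dropna()
    if len(r) == 0 or len(s) == 0:
        raise ValueError("both columns must be nonempty")
    if not (pd.api.types.is_numeric_dtype(r) and pd.api.types.is_numeric_dtype(s)):
        raise TypeError("ks_complement requires numeric columns")
    stat = stats.ks_2samp(r.to_numpy(dtype=float), s.to_numpy(dtype=float),
                          method="asymp").statistic
    return float(1.0 - stat)


def tv_complement(real: pd.Series, synthetic: pd.Series) -> float:
    """1 minus the total variation distance between category frequencies."""
    r = pd.Series(real).dropna()
    s = pd.Series(synthetic).dropna()
    if len(r) == 0 or len(s) == 0:
        raise ValueError("both columns must be nonempty")
    pr = r.value_counts(normalize=True)
    ps = s.value_counts(normalize=True)
    cats = pr.index.union(ps.index)
    tv = 0.5 * float(np.abs(pr.reindex(cats, fill_value=0.0)
                            - ps.reindex(cats, fill_value=0.0)).sum())
    return 1.0 - tv


# ---------------------------------------------------------------------------
# Pair trends
# ---------------------------------------------------------------------------

def _bin_numeric(real: pd.Series, synthetic: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Quantile-bin both columns by edges computed on the real column."""
    edges = np.unique(np.quantile(real.dropna().to_numpy(dtype=float),
                                  np.linspace(0, 1, N_QUANTILE_BINS + 1)))
    if len(edges) < 2:
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    def cut(s: pd.Series) -> pd.Series:
        v = np.clip(s.to_numpy(dtype=float), edges[0], edges[-1])
        return pd.Series(np.digitize(v, edges[1:-1]), index=s.index)
    return cut(real), cut(synthetic)


def _contingency_similarity(ra: pd.Series, rb: pd.Series,
                            sa: pd.Series, sb: pd.Series) -> float:
    jr = pd.crosstab(ra, rb, normalize=True)
    js = pd.crosstab(sa, sb, normalize=True)
    rows = jr.index.union(js.index)
    cols = jr.columns.union(js.columns)
    jr = jr.reindex(index=rows, columns=cols, fill_value=0.0)
    js = js.reindex(index=rows, columns=cols, fill_value=0.0)
    return 1.0 - 0.5 * float(np.abs(jr.to_numpy() - js.to_numpy()).sum())


def pair_trend(real: pd.DataFrame, synthetic: pd.DataFrame,
               col_a: str, col_b: str,
               types: dict[str, str] | None = None) -> float:
    """Dependence-preservation score for one column pair.

    Numeric–numeric pairs: ``1 - |rho_real - rho_syn| / 2`` (Pearson).
    Pairs involving a categorical (or a constant numeric) column: joint
    contingency similarity, with numeric columns discretized into
    real-quantile bins.
    """
    types = types or column_types(real)
    a_num = types[col_a] == "numeric"
    b_num = types[col_b] == "numeric"
    ra, rb = real[col_a], real[col_b]
    sa, sb = synthetic[col_a], synthetic[col_b]
    if a_num and b_num:
        const = (ra.nunique(dropna=True) < 2 or rb.nunique(dropna=True) < 2
                 or sa.nunique(dropna=True) < 2 or sb.nunique(dropna=True) < 2)
        if not const:
            rho_r = float(ra.corr(rb))
            rho_s = float(sa.corr(sb))
            if not (np.isnan(rho_r) or np.isnan(rho_s)):
                return 1.0 - abs(rho_r - rho_s) / 2.0
    if a_num:
        ra, sa = _bin_numeric(real[col_a], synthetic[col_a])
    if b_num:
        rb, sb = _bin_numeric(real[col_b], synthetic[col_b])
    return _contingency_similarity(ra, rb, sa, sb)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class QualityReport:
    column_shapes: dict[str, float]
    pair_trends: pd.DataFrame       # symmetric matrix, columns x columns
    shapes_overall: float
    trends_overall: float
    quality_overall: float

    def to_dict(self) -> dict:
        return {"column_shapes": self.column_shapes,
                "shapes_overall": self.shapes_overall,
                "trends_overall": self.trends_overall,
                "quality_overall": self.quality_overall}


def quality_overall(shapes_overall: float, trends_overall: float) -> float:
    """The overall quality score: mean of the two subscores."""
    return (shapes_overall + trends_overall) / 2.0


def quality_report(real: pd.DataFrame, synthetic: pd.DataFrame,
                   categorical: list[str] | None = None,
                   id_columns: tuple[str, ...] = ("subject_id",),
                   ) -> QualityReport:
    """Column-shape and column-pair-trend fidelity, averaged per the study rules."""
    cols = [c for c in real.columns if c not in id_columns]
    if sorted(cols) != sorted(c for c in synthetic.columns if c not in id_columns):
        raise ValueError("real and synthetic tables must share a schema")
    types = column_types(real[cols], categorical)

    shapes = {}
    for col in cols:
        if types[col] == "numeric":
            shapes[col] = ks_complement(real[col], synthetic[col])
        else:
            shapes[col] = tv_complement(real[col], synthetic[col])

    # Pre-compute Pearson matrices for the numeric-numeric fast path.
    matrix = pd.DataFrame(np.ones((len(cols), len(cols))), index=cols, columns=cols)
    pair_scores = []
    num_cols = [c for c in cols if types[c] == "numeric"
                and real[c].nunique(dropna=True) > 1
                and synthetic[c].nunique(dropna=True) > 1]
    corr_r = real[num_cols].corr() if num_cols else pd.DataFrame()
    corr_s = synthetic[num_cols].corr() if num_cols else pd.DataFrame()
    num_set = set(num_cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if a in num_set and b in num_set:
                rho_r, rho_s = corr_r.loc[a, b], corr_s.loc[a, b]
                if np.isnan(rho_r) or np.isnan(rho_s):
                    score = pair_trend(real, synthetic, a, b, types)
                else:
                    score = 1.0 - abs(float(rho_r) - float(rho_s)) / 2.0
            else:
                score = pair_trend(real, synthetic, a, b, types)
            matrix.loc[a, b] = matrix.loc[b, a] = score
            pair_scores.append(score)

    shapes_overall = float(np.mean(list(shapes.values())))
    trends_overall = float(np.mean(pair_scores)) if pair_scores else 1.0
    return QualityReport(
        column_shapes=shapes, pair_trends=matrix,
        shapes_overall=shapes_overall, trends_overall=trends_overall,
        quality_overall=quality_overall(shapes_overall, trends_overall))


@dataclass
class DiagnosticReport:
    validity: dict[str, float]
    validity_overall: float
    structure_score: float
    diagnostic_overall: float

    def to_dict(self) -> dict:
        return {"validity": self.validity,
                "validity_overall": self.validity_overall,
                "structure_score": self.structure_score,
                "diagnostic_overall": self.diagnostic_overall}


def table_structure(real: pd.DataFrame, synthetic: pd.DataFrame) -> float:
    """Column-set congruence: |shared columns| / |union of columns|."""
    r, s = set(real.columns), set(synthetic.columns)
    if not r | s:
        return 1.0
    return len(r & s) / len(r | s)


def diagnostic_report(real: pd.DataFrame, synthetic: pd.DataFrame,
                      categorical: list[str] | None = None,
                      id_columns: tuple[str, ...] = ("subject_id",),
                      ) -> DiagnosticReport:
    """Data-validity (boundary/category adherence) and structure congruence."""
    shared = [c for c in real.columns
              if c in synthetic.columns and c not in id_columns]
    types = column_types(real[shared], categorical)
    validity = {}
    for col in shared:
        s = synthetic[col].dropna()
        if len(s) == 0:
            validity[col] = 1.0
            continue
        if types[col] == "numeric":
            lo, hi = real[col].min(), real[col].max()
            validity[col] = float(((s >= lo) & (s <= hi)).mean())
        else:
            allowed = set(real[col].dropna().unique())
            validity[col] = float(s.isin(allowed).mean())
    validity_overall = float(np.mean(list(validity.values()))) if validity else 1.0
    structure = table_structure(real.drop(columns=[c for c in id_columns
                                                   if c in real.columns]),
                                synthetic.drop(columns=[c for c in id_columns
                                                        if c in synthetic.columns]))
    return DiagnosticReport(
        validity=validity, validity_overall=validity_overall,
        structure_score=structure,
        diagnostic_overall=(validity_overall + structure) / 2.0)


# ---------------------------------------------------------------------------
# Privacy metrics
# ---------------------------------------------------------------------------

def new_row_synthesis(real: pd.DataFrame, synthetic: pd.DataFrame,
                      numeric_tol: float = NEW_ROW_NUMERIC_TOL,
                      categorical: list[str] | None = None,
                      id_columns: tuple[str, ...] = ("subject_id",)) -> float:
    """Fraction of synthetic rows matching *no* real row.

    A match requires categorical equality and numeric agreement within
    ``numeric_tol`` times the real column range.
    """
    cols = [c for c in real.columns if c not in id_columns]
    if sorted(cols) != sorted(c for c in synthetic.columns if c not in id_columns):
        raise ValueError("real and synthetic tables must share a schema")
    if len(synthetic) == 0:
        return 1.0
    types = column_types(real[cols], categorical)
    match = np.ones((len(synthetic), len(real)), dtype=bool)
    for col in cols:
        r = real[col].to_numpy()
        s = synthetic[col].to_numpy()
        if types[col] == "numeric":
            r = r.astype(float)
            s = s.astype(float)
            tol = numeric_tol * float(np.nanmax(r) - np.nanmin(r)) if len(r) else 0.0
            col_match = np.abs(s[:, None] - r[None, :]) <= tol
            col_match |= np.isnan(s)[:, None] & np.isnan(r)[None, :]
        else:
            col_match = s[:, None] == r[None, :]
        match &= col_match
        if not match.any():
            break
    matched = match.any(axis=1)
    return float(1.0 - matched.mean())


def _one_hot_align(real: pd.DataFrame, synthetic: pd.DataFrame,
                   categorical: list[str] | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Jointly one-hot encode two same-schema tables; returns float arrays."""
    types = column_types(real, categorical)
    cats = [c for c, t in types.items() if t == "categorical"]
    both = pd.concat([real, synthetic], axis=0, ignore_index=True)
    enc = pd.get_dummies(both, columns=cats, dtype=float)
    enc = enc.astype(float).fillna(enc.median(numeric_only=True))
    arr = enc.to_numpy()
    return arr[:len(real)], arr[len(real):]


def detection_score(real: pd.DataFrame, synthetic: pd.DataFrame,
                    classifier: str = "logistic", seed: int = 0,
                    categorical: list[str] | None = None,
                    id_columns: tuple[str, ...] = ("subject_id",),
                    n_folds: int = 5) -> float:
    """1 minus the rescaled cross-validated AUC of a real-vs-synthetic classifier.

    ``score = 1 - 2 * (max(AUC, 0.5) - 0.5)``: 1 means the twin is
    indistinguishable from the original, 0 means perfectly separable.
    """
    if len(real) < 20 or len(synthetic) < 20:
        raise ValueError("both tables need at least 20 rows for detection")
    r = real.drop(columns=[c for c in id_columns if c in real.columns])
    s = synthetic.drop(columns=[c for c in id_columns if c in synthetic.columns])
    Xr, Xs = _one_hot_align(r, s, categorical)
    X = np.vstack([Xr, Xs])
    y = np.concatenate([np.zeros(len(Xr)), np.ones(len(Xs))])

    if classifier == "logistic":
        make = lambda: LogisticRegression(max_iter=1000)
    elif classifier == "svc":
        make = lambda: SVC(gamma="scale")
    else:
        raise ValueError("classifier must be 'logistic' or 'svc'")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    for train, test in skf.split(X, y):
        scaler = StandardScaler().fit(X[train])
        clf = make().fit(scaler.transform(X[train]), y[train])
        Xt = scaler.transform(X[test])
        if hasattr(clf, "predict_proba"):
            pred = clf.predict_proba(Xt)[:, 1]
        else:
            pred = clf.decision_function(Xt)
        aucs.append(roc_auc_score(y[test], pred))
    auc = float(np.mean(aucs))
    return 1.0 - 2.0 * (max(auc, 0.5) - 0.5)


def inference_privacy_categorical(real: pd.DataFrame, synthetic: pd.DataFrame,
                                  key_cols: list[str], sensitive_col: str) -> float:
    """CAP-style attack: match real rows to synthetic rows on the keys and
    guess the modal sensitive value; score = 1 - accuracy.

    Real rows with no key match in the synthetic table count as protected.
    """
    if sensitive_col in key_cols:
        raise ValueError("sensitive column must not be among the keys")
    for c in key_cols + [sensitive_col]:
        if c not in real.columns or c not in synthetic.columns:
            raise KeyError(f"column {c!r} missing")
    if len(real) == 0:
        return 1.0

    def modal(s: pd.Series):
        counts = s.value_counts()
        top = counts[counts == counts.iloc[0]]
        return sorted(top.index, key=str)[0]

    guesses = (synthetic.groupby(key_cols, dropna=False, observed=True)[sensitive_col]
               .agg(modal).rename("_guess").reset_index())
    merged = real[key_cols + [sensitive_col]].merge(guesses, on=key_cols, how="left")
    correct = (merged["_guess"].notna()
               & (merged["_guess"] == merged[sensitive_col])).mean()
    return float(1.0 - correct)


def inference_privacy_numeric(real: pd.DataFrame, synthetic: pd.DataFrame,
                              key_cols: list[str], sensitive_col: str,
                              categorical: list[str] | None = None) -> float:
    """Regression attack: train keys -> sensitive on synthetic, evaluate on real.

    ``score = min(1, RMSE_attacker / RMSE_baseline)`` with the baseline
    predicting the real mean; 1 means the attacker learned nothing.
    """
    if sensitive_col in key_cols:
        raise ValueError("sensitive column must not be among the keys")
    y_real = real[sensitive_col].to_numpy(dtype=float)
    y_syn = synthetic[sensitive_col].to_numpy(dtype=float)
    baseline = float(np.sqrt(np.mean((y_real - y_real.mean()) ** 2)))
    if baseline == 0.0:
        warnings.warn("zero-variance sensitive column; score 0 by convention")
        return 0.0
    Xr, Xs = _one_hot_align(real[key_cols], synthetic[key_cols], categorical)
    model = LinearRegression().fit(Xs, y_syn)
    rmse = float(np.sqrt(np.mean((model.predict(Xr) - y_real) ** 2)))
    return min(1.0, rmse / baseline)


# ---------------------------------------------------------------------------
# ML efficacy (train on synthetic, test on real)
# ---------------------------------------------------------------------------

BINARY_ALGORITHMS = ("adaboost", "decision_tree", "logistic_regression", "mlp")
MULTICLASS_ALGORITHMS = ("decision_tree", "mlp")


def _make_classifier(name: str, seed: int):
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "logistic_regression":
        return LogisticRegression(max_iter=1000)
    if name == "mlp":
        return MLPClassifier(hidden_layer_sizes=(64,), max_iter=300,
                             random_state=seed)
    raise ValueError(name)


def _target_type(real: pd.Series, categorical: bool) -> str:
    nun = real.nunique(dropna=True)
    if not categorical and pd.api.types.is_numeric_dtype(real) and nun > 10:
        return "numeric"
    return "binary" if nun <= 2 else "multiclass"


def ml_efficacy(real_test: pd.DataFrame, synthetic_train: pd.DataFrame,
                target_col: str, seed: int = 0,
                categorical: list[str] | None = None,
                id_columns: tuple[str, ...] = ("subject_id",)) -> dict:
    """Train-on-synthetic / test-on-real scores for one target.

    Binary targets average four classifiers, multiclass two (macro-F1);
    a numeric target is scored by a single linear regression (R^2 clipped
    to [0, 1]).  Returns ``{"target_type", "scores", "overall"}``.
    """
    drop = [c for c in id_columns if c in real_test.columns]
    real_test = real_test.drop(columns=drop)
    synthetic_train = synthetic_train.drop(
        columns=[c for c in id_columns if c in synthetic_train.columns])
    feats = [c for c in real_test.columns if c != target_col]
    cat_feats = [c for c in (categorical or []) if c != target_col]
    Xr, Xs = _one_hot_align(real_test[feats], synthetic_train[feats], cat_feats)
    scaler = StandardScaler().fit(Xs)
    Xr, Xs = scaler.transform(Xr), scaler.transform(Xs)
    y_real = real_test[target_col]
    y_syn = synthetic_train[target_col]

    explicit_cat = categorical is not None and target_col in categorical
    ttype = _target_type(y_real, explicit_cat)
    scores: dict[str, float] = {}
    if ttype == "numeric":
        model = LinearRegression().fit(Xs, y_syn.to_numpy(dtype=float))
        r2 = r2_score(y_real.to_numpy(dtype=float), model.predict(Xr))
        scores["linear_regression"] = float(np.clip(r2, 0.0, 1.0))
    else:
        algos = BINARY_ALGORITHMS if ttype == "binary" else MULTICLASS_ALGORITHMS
        for name in algos:
            if y_syn.nunique(dropna=True) < 2:
                warnings.warn(f"target constant in synthetic data; "
                              f"{name} scores 0")
                scores[name] = 0.0
                continue
            clf = _make_classifier(name, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(Xs, y_syn.astype(str))
            pred = clf.predict(Xr)
            scores[name] = float(f1_score(y_real.astype(str), pred,
                                          average="macro"))
    return {"target_type": ttype, "scores": scores,
            "overall": float(np.mean(list(scores.values())))}


@dataclass
class UtilityReport:
    """Per-target ML-efficacy scores plus per-target overalls."""

    targets: dict[str, dict] = field(default_factory=dict)

    def overall(self, target: str) -> float:
        return self.targets[target]["overall"]

    def to_dict(self) -> dict:
        return self.targets


def utility_report(real_test: pd.DataFrame, synthetic_train: pd.DataFrame,
                   target_cols: list[str], seed: int = 0,
                   categorical: list[str] | None = None) -> UtilityReport:
    rep = UtilityReport()
    for t in target_cols:
        rep.targets[t] = ml_efficacy(real_test, synthetic_train, t, seed=seed,
                                     categorical=categorical)
    return rep


# ---------------------------------------------------------------------------
# Privacy aggregation
# ---------------------------------------------------------------------------

@dataclass
class PrivacyReport:
    new_row_synthesis: float
    detection_logistic: float
    detection_svc: float
    table_structure: float
    inference_scores: dict[str, float] = field(default_factory=dict)
    overall_privacy: float = float("nan")

    def __post_init__(self) -> None:
        if np.isnan(self.overall_privacy):
            self.overall_privacy = overall_privacy(
                self.new_row_synthesis, self.detection_logistic,
                self.detection_svc, self.table_structure)

    def to_dict(self) -> dict:
        return {"new_row_synthesis": self.new_row_synthesis,
                "detection_logistic": self.detection_logistic,
                "detection_svc": self.detection_svc,
                "table_structure": self.table_structure,
                "inference_scores": self.inference_scores,
                "overall_privacy": self.overall_privacy}


def overall_privacy(new_row: float, det_logistic: float, det_svc: float,
                    structure: float) -> float:
    """Arithmetic mean of the four type-agnostic privacy components."""
    for v in (new_row, det_logistic, det_svc, structure):
        if v is None or np.isnan(v):
            raise ValueError("all four privacy components are required")
    return float(np.mean([new_row, det_logistic, det_svc, structure]))


def privacy_report(real: pd.DataFrame, synthetic: pd.DataFrame, seed: int = 0,
                   categorical: list[str] | None = None,
                   key_cols: list[str] | None = None,
                   sensitive_cols: list[str] | None = None,
                   id_columns: tuple[str, ...] = ("subject_id",)) -> PrivacyReport:
    """Compute the four global privacy components plus optional inference attacks.

    Default quasi-identifier keys are age, gender, race and marital status.
    """
    nrs = new_row_synthesis(real, synthetic, categorical=categorical,
                            id_columns=id_columns)
    det_log = detection_score(real, synthetic, "logistic", seed=seed,
                              categorical=categorical, id_columns=id_columns)
    det_svc = detection_score(real, synthetic, "svc", seed=seed,
                              categorical=categorical, id_columns=id_columns)
    struct = table_structure(
        real.drop(columns=[c for c in id_columns if c in real.columns]),
        synthetic.drop(columns=[c for c in id_columns if c in synthetic.columns]))
    inference: dict[str, float] = {}
    if sensitive_cols:
        keys = key_cols or [c for c in ("age", "gender", "race", "marital")
                            if c in real.columns]
        for col in sensitive_cols:
            keys_c = [k for k in keys if k != col]
            if column_types(real[[col]], categorical)[col] == "categorical":
                inference[col] = inference_privacy_categorical(
                    real, synthetic, keys_c, col)
            else:
                inference[col] = inference_privacy_numeric(
                    real, synthetic, keys_c, col, categorical=categorical)
    return PrivacyReport(new_row_synthesis=nrs, detection_logistic=det_log,
                         detection_svc=det_svc, table_structure=struct,
                         inference_scores=inference)
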