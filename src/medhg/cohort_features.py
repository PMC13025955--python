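"""Outcome labels, encounter feature matrix, cohort summaries and splits.

The featurizer follows the usual tabular-EHR preprocessing recipe: filter
implausible values, impute continuous features with the training mean and
standardize them (population SD), map missing or unseen categorical levels
to an explicit ``Unknown`` level and one-hot encode.  All statistics are
learned on training rows only, so validation/test rows can never leak into
the transformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic_ehr import inject_missingness

#: default plausibility ranges used to null out implausible raw values
DEFAULT_PLAUSIBILITY = {
    "bmi": (10.0, 80.0),
    "height": (120.0, 220.0),
    "weight": (30.0, 300.0),
    "age": (18.0, 110.0),
}

CONTINUOUS_COVARIATES = (
    "age", "height", "weight", "bmi", "cci", "asa_ps",
    "start_to_induction_min", "induction_to_incision_min",
    "incision_to_dressing_min", "dressing_to_emergence_min",
    "emergence_to_end_min", "anesthesia_duration_min",
    "preop_intermediate_hours", "preop_intensive_hours", "preop_acute_hours",
)
CATEGORICAL_COVARIATES = (
    "sex", "race_ethnicity", "marital_status", "anesthesia_type",
    "day_of_week", "day_type", "admission_source",
)
BINARY_COVARIATES = (
    "flag_chf", "flag_copd", "flag_diabetes", "flag_cancer", "flag_delirium",
    "block_flag",
)


# ---------------------------------------------------------------------------
# outcome labels
# ---------------------------------------------------------------------------

def derive_outcomes(encounters: pd.DataFrame, quantile: float = 0.75,
                    reference_rows=None) -> pd.DataFrame:
    """Derive PLOS / 30-day / 90-day mortality labels.

    PLOS is 1 iff ``postop_los`` strictly exceeds the ``quantile`` of LOS
    over ``reference_rows`` (encounter ids; defaults to all rows).  The
    quantile uses the linear-interpolation convention.  Mortality labels
    are inclusive: ``death_offset <= 30`` / ``<= 90`` days.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    if encounters["postop_los"].isna().any():
        raise ValueError("postop_los must be present for all rows")
    if reference_rows is None:
        ref = encounters
    else:
        reference_rows = list(reference_rows)
        if len(reference_rows) == 0:
            raise ValueError("reference_rows is empty")
        ref = encounters[encounters["encounter_id"].isin(reference_rows)]
        if ref.empty:
            raise ValueError("reference_rows matched no encounters")
    threshold = float(np.quantile(ref["postop_los"].to_numpy(float), quantile))
    death = encounters["death_offset"]
    return pd.DataFrame({
        "encounter_id": encounters["encounter_id"].to_numpy(),
        "plos": (encounters["postop_los"] > threshold).astype(int).to_numpy(),
        "mort30": ((death.notna()) & (death <= 30)).astype(int).to_numpy(),
        "mort90": ((death.notna()) & (death <= 90)).astype(int).to_numpy(),
        "plos_threshold_days": threshold,
    })


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

class EncounterFeaturizer(BaseEstimator, TransformerMixin):
    """Impute / encode / standardize encounter covariates.

    Parameters
    ----------
    continuous, categorical, binary:
        Column rosters; defaults cover the full synthetic schema, columns
        absent from the input are silently skipped.
    plausibility:
        {column: (lo, hi)} ranges; raw values outside the range are treated
        as missing both when fitting and when transforming.

    Fitted attributes
    -----------------
    means_, sds_ : training mean and population SD per kept continuous column
    categories_  : training category list per categorical column (plus "Unknown")
    dropped_     : continuous columns dropped for zero variance / all-missing
    feature_names_ : output column order
    """

    def __init__(self, continuous=CONTINUOUS_COVARIATES,
                 categorical=CATEGORICAL_COVARIATES,
                 binary=BINARY_COVARIATES,
                 plausibility=None):
        self.continuous = continuous
        self.categorical = categorical
        self.binary = binary
        self.plausibility = plausibility

    def _ranges(self):
        return DEFAULT_PLAUSIBILITY if self.plausibility is None else self.plausibility

    def _clean_numeric(self, col: pd.Series, name: str) -> pd.Series:
        x = pd.to_numeric(col, errors="coerce")
        lo, hi = self._ranges().get(name, (-np.inf, np.inf))
        return x.where((x >= lo) & (x <= hi))

    def fit(self, X: pd.DataFrame, y=None):
        if len(X) == 0:
            raise ValueError("cannot fit featurizer on an empty frame")
        self.means_, self.sds_, self.dropped_ = {}, {}, []
        for c in self.continuous:
            if c not in X.columns:
                continue
            x = self._clean_numeric(X[c], c)
            if x.notna().sum() == 0:
                warnings.warn(f"column {c!r} all missing on training rows; dropped")
                self.dropped_.append(c)
                continue
            sd = float(x.std(ddof=0))
            if sd == 0.0:
                warnings.warn(f"column {c!r} has zero variance on training rows; dropped")
                self.dropped_.append(c)
                continue
            self.means_[c] = float(x.mean())
            self.sds_[c] = sd
        self.categories_ = {}
        for c in self.categorical:
            if c not in X.columns:
                continue
            levels = sorted(X[c].dropna().astype(str).unique().tolist())
            if "Unknown" not in levels:
                levels.append("Unknown")
            self.categories_[c] = levels
        self.binary_cols_ = [c for c in self.binary if c in X.columns]
        self.feature_names_ = (
            list(self.means_)
            + [f"{c}={lvl}" for c in self.categories_ for lvl in self.categories_[c]]
            + self.binary_cols_
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "means_"):
            raise RuntimeError("featurizer is not fitted")
        cols = {}
        for c, mu in self.means_.items():
            x = self._clean_numeric(X[c], c).fillna(mu)
            cols[c] = (x - mu) / self.sds_[c]
        for c, levels in self.categories_.items():
            raw = X[c].astype(object).where(X[c].notna(), "Unknown").astype(str)
            raw = raw.where(raw.isin(levels), "Unknown")
            for lvl in levels:
                cols[f"{c}={lvl}"] = (raw == lvl).astype(float)
        for c in self.binary_cols_:
            cols[c] = pd.to_numeric(X[c], errors="coerce").fillna(0.0).astype(float)
        out = pd.DataFrame(cols, index=X.index)[self.feature_names_]
        if "encounter_id" in X.columns:
            out.index = pd.Index(X["encounter_id"], name="encounter_id")
        return out

    def fitted_stats(self) -> dict:
        return {"means": self.means_, "sds": self.sds_,
                "categories": self.categories_, "dropped": self.dropped_,
                "binary": self.binary_cols_}


def build_feature_matrix(encounters: pd.DataFrame, train_ids,
                         featurizer: EncounterFeaturizer | None = None):
    """Fit a featurizer on ``train_ids`` rows and transform every encounter.

    Returns ``(matrix, featurizer)``; ``matrix`` is indexed by encounter id
    in the input row order.
    """
    train_ids = list(train_ids)
    if not train_ids:
        raise ValueError("train_ids is empty")
    fz = featurizer or EncounterFeaturizer()
    train_rows = encounters[encounters["encounter_id"].isin(train_ids)]
    fz.fit(train_rows)
    return fz.transform(encounters), fz


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def percent(count: int, total: int) -> float:
    """Percentage rounded to two decimals, the convention of cohort tables."""
    return round(100.0 * count / total, 2) if total else 0.0


_pct = percent


def cohort_summary(encounters: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages by demographic strata and outcome.

    Demographic strata are patient-level (each patient counted once, at
    their first encounter); outcomes are encounter-level.
    """
    rows = []
    patients = encounters.drop_duplicates("patient_id")
    n_pat, n_enc = len(patients), len(encounters)
    rows.append(("patient", "total", "", n_pat, 100.0))
    for stratum in ("sex", "race_ethnicity"):
        if stratum in patients.columns:
            for level, cnt in patients[stratum].value_counts(dropna=False).items():
                rows.append(("patient", stratum, str(level), int(cnt), _pct(int(cnt), n_pat)))
    rows.append(("encounter", "total", "", n_enc, 100.0))
    merged = encounters[["encounter_id"]].merge(labels, on="encounter_id")
    for outcome in ("plos", "mort30", "mort90"):
        pos = int(merged[outcome].sum())
        rows.append(("encounter", outcome, "yes", pos, _pct(pos, n_enc)))
        rows.append(("encounter", outcome, "no", n_enc - pos, _pct(n_enc - pos, n_enc)))
    return pd.DataFrame(rows, columns=["level", "stratum", "value", "count", "percent"])


def mask_features(encounters: pd.DataFrame, mask_spec, seed: int) -> pd.DataFrame:
    """Randomly mask already-recorded features (robustness experiment)."""
    return inject_missingness(encounters, mask_spec, seed)


# ---------------------------------------------------------------------------
# resampling and splits
# ---------------------------------------------------------------------------

def resample_training(ids, labels, mode: str, seed: int):
    """Balance training ids by undersampling negatives or oversampling positives.

    ``labels`` maps id -> {0,1} (mapping or aligned sequence).  Returns a
    list of ids (a multiset under oversampling).
    """
    ids = list(ids)
    if isinstance(labels, (pd.Series, dict)):
        lab = np.array([int(labels[i]) for i in ids])
    else:
        lab = np.asarray(labels, dtype=int)
        if len(lab) != len(ids):
            raise ValueError("labels length does not match ids")
    if mode == "none":
        return ids
    pos = [i for i, l in zip(ids, lab) if l == 1]
    neg = [i for i, l in zip(ids, lab) if l == 0]
    if not pos or not neg:
        raise ValueError("resampling requires both classes in the training ids")
    rng = np.random.default_rng(seed)
    if mode == "undersample":
        keep = rng.choice(len(neg), size=len(pos), replace=False)
        return pos + [neg[k] for k in sorted(keep)]
    if mode == "oversample":
        extra = rng.choice(len(pos), size=len(neg), replace=True)
        return [pos[k] for k in extra] + neg
    raise ValueError(f"unknown resampling mode {mode!r}")


@dataclass
class SplitIndices:
    train: list
    validation: list
    test: list
    ratios: tuple = (8, 1, 1)
    seed: int = 0
    group_by: str = "encounter"
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"train": list(self.train), "validation": list(self.validation),
                "test": list(self.test), "ratios": list(self.ratios),
                "seed": self.seed, "group_by": self.group_by}


def _apportion(n: int, ratios) -> list:
    """Largest-remainder apportionment of n items into len(ratios) buckets."""
    ratios = np.asarray(ratios, dtype=float)
    quota = n * ratios / ratios.sum()
    base = np.floor(quota).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(quota - base))
    for k in range(rem):
        base[order[k]] += 1
    # never leave a bucket empty when there are enough items to go round
    while n >= len(base) and base.min() == 0:
        base[np.argmax(base)] -= 1
        base[np.argmin(base)] += 1
    return base.tolist()


def split_indices(encounters: pd.DataFrame, ratios=(8, 1, 1), seed: int = 0,
                  group_by: str = "encounter") -> SplitIndices:
    """Random train/validation/test split of encounter ids.

    With ``group_by="patient"`` all encounters of a patient land in one
    split (patients are shuffled, then packed into splits in ratio order).
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    rng = np.random.default_rng(seed)
    enc_ids = encounters["encounter_id"].to_numpy()
    if group_by == "encounter":
        perm = rng.permutation(len(enc_ids))
        sizes = _apportion(len(enc_ids), ratios)
        cuts = np.cumsum([0] + sizes)
        parts = [enc_ids[perm[cuts[i]:cuts[i + 1]]].tolist() for i in range(3)]
    elif group_by == "patient":
        patients = encounters["patient_id"].unique()
        if len(patients) < 3:
            raise ValueError("need at least as many patients as splits")
        perm = rng.permutation(len(patients))
        n_pat_per = _apportion(len(patients), ratios)
        cuts = np.cumsum([0] + n_pat_per)
        parts = []
        for i in range(3):
            chosen = set(patients[perm[cuts[i]:cuts[i + 1]]])
            parts.append(encounters.loc[
                encounters["patient_id"].isin(chosen), "encounter_id"].tolist())
    else:
        raise ValueError(f"unknown group_by {group_by!r}")
    if min(len(p) for p in parts) == 0:
        raise ValueError("a split came out empty; fewer groups than splits")
    return SplitIndices(*parts, ratios=tuple(ratios), seed=seed, group_by=group_by)
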