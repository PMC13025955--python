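"""Synthetic surgical-EHR cohort generator with planted outcome effects.

Emits three event tables that mimic the schema of a perioperative EHR
extract: one row per surgical hospital encounter (demographics,
perioperative covariates, postoperative length of stay, death offset),
provider-to-encounter assignments in five role groups, and pre-operative
care-unit transfer events in three acuity levels.

Outcome risk is planted on the log-odds scale as a linear combination of
standardized covariate and connectivity terms, so that downstream models
and explanation methods can be validated against a known ground truth:

    logit P(outcome) = baseline_logit + sum_j w_j * z_j

where each ``z_j`` is a cohort-standardized covariate (age, CCI, ...) or
connectivity term (number of technician assignments, pre-op acute-unit
hours, ...).  Prolonged length of stay (PLOS) is realized by sampling the
post-operative LOS below/above a fixed threshold (default 6 days, the
75th-percentile convention for this cohort design); 30- and 90-day
mortality are nested by drawing a death offset on [1, 30] or [31, 90].
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

PROVIDER_ROLES = ("surgical_team", "other_clinician", "nurse", "technician", "other")
CARE_UNITS = ("intermediate", "intensive", "acute")

#: connectivity terms resolvable by name in ``effect_weights``
CONNECTIVITY_TERMS = (
    tuple(f"n_assign_{r}" for r in PROVIDER_ROLES)
    + ("n_providers", "n_transfers")
    + tuple(f"n_stays_{u}" for u in CARE_UNITS)
    + tuple(f"{u}_hours" for u in CARE_UNITS)
)

_NUMERIC_COVARIATES = (
    "age", "height", "weight", "bmi", "cci", "asa_ps",
    "start_to_induction_min", "induction_to_incision_min",
    "incision_to_dressing_min", "dressing_to_emergence_min",
    "emergence_to_end_min", "anesthesia_duration_min",
    "preop_intermediate_hours", "preop_intensive_hours", "preop_acute_hours",
)


def _default_pools() -> dict:
    return {"surgical_team": 80, "other_clinician": 120, "nurse": 200,
            "technician": 90, "other": 60}


def _default_role_counts() -> dict:
    # per-role inclusive (min, max) providers per encounter, sampled
    # independently so connectivity terms are identifiable
    return {"surgical_team": (1, 3), "other_clinician": (1, 3),
            "nurse": (1, 4), "technician": (0, 2), "other": (0, 2)}


def _default_baselines() -> dict:
    # prevalences matching the cohort design: 25% PLOS, 5.32% 90-day mortality
    return {"plos": float(logit(0.25)), "mort90": float(logit(0.0532))}


def _default_effects() -> dict:
    return {
        "plos": {"acute_hours": 0.8, "n_stays_acute": 0.4, "cci": 0.4,
                 "age": 0.2, "bmi": 0.15, "n_providers": 0.2},
        "mort90": {"age": 0.8, "cci": 0.6, "asa_ps": 0.5,
                   "n_assign_technician": 0.3, "intensive_hours": 0.3},
    }


def _default_missingness() -> dict:
    # rates used by the masking/robustness experiment design
    return {"bmi": 0.043, "height": 0.043, "marital_status": 0.0211,
            "cci": 0.083, "asa_ps": 0.017}


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic cohort; defaults are the study conditions.

    Attributes
    ----------
    n_patients:
        Number of distinct patients; encounters per patient follow
        ``1 + Poisson(encounters_per_patient - 1)``.
    provider_pool_sizes:
        Shared provider pool per role; reuse across encounters induces the
        cross-encounter provider co-occurrence the holistic provider graph
        needs.
    team_size_range:
        Inclusive (min, max) total providers per encounter, implied by the
        per-role ranges in ``role_count_ranges`` (roles are sampled
        independently; at least one surgical-team member by default).
    transfer_rate:
        Mean number of pre-operative unit stays per encounter (Poisson).
    baseline_logit / effect_weights:
        Per-outcome intercept and {term: log-odds weight} maps; keys of the
        weight maps must be numeric covariates or ``CONNECTIVITY_TERMS``.
    missingness_rates:
        MCAR masking fractions applied to encounter features after outcome
        generation.
    """

    n_patients: int = 2000
    encounters_per_patient: float = 1.33
    provider_pool_sizes: Mapping[str, int] = field(default_factory=_default_pools)
    team_size_range: tuple = (3, 14)
    role_count_ranges: Mapping[str, tuple] = field(default_factory=_default_role_counts)
    transfer_rate: float = 1.5
    plos_threshold_days: float = 6.0
    baseline_logit: Mapping[str, float] = field(default_factory=_default_baselines)
    mort30_fraction: float = 0.594
    effect_weights: Mapping[str, Mapping[str, float]] = field(default_factory=_default_effects)
    missingness_rates: Mapping[str, float] = field(default_factory=_default_missingness)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.encounters_per_patient < 1:
            raise ValueError("encounters_per_patient must be >= 1")
        for role in PROVIDER_ROLES:
            if self.provider_pool_sizes.get(role, 0) < 1:
                raise ValueError(f"provider_pool_sizes[{role!r}] must be >= 1")
        lo, hi = self.team_size_range
        if not (1 <= lo <= hi):
            raise ValueError("team_size_range must satisfy 1 <= min <= max")
        total_lo = sum(self.role_count_ranges[r][0] for r in PROVIDER_ROLES)
        total_hi = sum(self.role_count_ranges[r][1] for r in PROVIDER_ROLES)
        for r in PROVIDER_ROLES:
            a, b = self.role_count_ranges[r]
            if not (0 <= a <= b):
                raise ValueError(f"role_count_ranges[{r!r}] must satisfy 0 <= min <= max")
        if total_lo < lo or total_hi > hi:
            raise ValueError("role_count_ranges totals fall outside team_size_range")
        if self.transfer_rate < 0:
            raise ValueError("transfer_rate must be >= 0")
        if not 0.0 <= self.mort30_fraction <= 1.0:
            raise ValueError("mort30_fraction must lie in [0, 1]")
        for feat, rate in self.missingness_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness_rates[{feat!r}] must lie in [0, 1]")
        known = set(_NUMERIC_COVARIATES) | set(CONNECTIVITY_TERMS)
        for outcome, weights in self.effect_weights.items():
            for term in weights:
                if term not in known:
                    raise ValueError(
                        f"effect_weights[{outcome!r}]: unknown term {term!r}; "
                        f"known terms: {sorted(known)}"
                    )

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


def planted_outcome_logit(encounter_row: Mapping[str, float],
                          connectivity_terms: Mapping[str, float],
                          config: SyntheticConfig,
                          outcome: str = "plos") -> float:
    """Linear planted log-odds for one encounter.

    ``encounter_row`` and ``connectivity_terms`` hold *standardized* term
    values; every key of ``config.effect_weights[outcome]`` must resolve in
    one of the two mappings.
    """
    weights = config.effect_weights.get(outcome, {})
    total = float(config.baseline_logit[outcome])
    for term, w in weights.items():
        if term in connectivity_terms:
            z = connectivity_terms[term]
        elif term in encounter_row:
            z = encounter_row[term]
        else:
            known = sorted(set(encounter_row) | set(connectivity_terms))
            raise KeyError(f"unknown term {term!r}; known terms: {known}")
        total += w * float(z)
    return total


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()  # population SD
    return np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd


def _empty_tables():
    enc = pd.DataFrame(columns=[
        "encounter_id", "patient_id", "age", "sex", "race_ethnicity",
        "marital_status", "height", "weight", "bmi", "cci", "asa_ps",
        "flag_chf", "flag_copd", "flag_diabetes", "flag_cancer", "flag_delirium",
        "start_to_induction_min", "induction_to_incision_min",
        "incision_to_dressing_min", "dressing_to_emergence_min",
        "emergence_to_end_min", "anesthesia_duration_min", "anesthesia_type",
        "block_flag", "day_of_week", "day_type", "admission_source",
        "preop_intermediate_hours", "preop_intensive_hours", "preop_acute_hours",
        "postop_los", "death_offset",
    ])
    asg = pd.DataFrame(columns=["encounter_id", "provider_id", "role"])
    trf = pd.DataFrame(columns=["encounter_id", "unit_type", "sequence_index", "duration"])
    return enc, asg, trf


def generate_cohort(config: SyntheticConfig):
    """Generate (encounters, assignments, transfers) tables.

    Fully deterministic given ``config.seed``; all type invariants hold on
    the output (BMI consistent with height/weight, non-negative intervals,
    contiguous transfer sequence indices, nested mortality labels).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.n_patients == 0:
        return _empty_tables()

    # ---- patients and encounter skeleton -----------------------------------
    n_enc_per_patient = 1 + rng.poisson(config.encounters_per_patient - 1.0,
                                        size=config.n_patients)
    patient_ids = np.repeat(
        [f"P{i:06d}" for i in range(config.n_patients)], n_enc_per_patient)
    n = len(patient_ids)
    enc_ids = np.array([f"E{i:07d}" for i in range(n)])

    # patient-level demographics, repeated across a patient's encounters
    p_age = np.clip(rng.normal(55.72, 18.01, config.n_patients), 18, 100)
    p_sex = rng.choice(["female", "male"], p=[0.6037, 0.3963], size=config.n_patients)
    p_race = rng.choice(["NHW", "NHB", "Hispanic", "Other"],
                        p=[0.6473, 0.1281, 0.0464, 0.1782], size=config.n_patients)
    p_marital = rng.choice(["married", "single", "divorced", "widowed"],
                           p=[0.48, 0.32, 0.12, 0.08], size=config.n_patients)
    p_height = np.where(p_sex == "male",
                        rng.normal(176, 7.5, config.n_patients),
                        rng.normal(162, 7.0, config.n_patients))
    p_height = np.clip(p_height, 130, 210)
    p_bmi_latent = np.clip(rng.normal(28.5, 6.0, config.n_patients), 14, 60)
    p_weight = p_bmi_latent * (p_height / 100.0) ** 2

    rep = np.repeat(np.arange(config.n_patients), n_enc_per_patient)
    age = np.round(p_age[rep], 1)
    height = np.round(p_height[rep], 1)
    weight = np.round(p_weight[rep], 1)
    bmi = np.round(weight / (height / 100.0) ** 2, 1)

    cci = np.minimum(rng.poisson(1.6, n), 16)
    asa_ps = rng.choice([1, 2, 3, 4, 5], p=[0.08, 0.32, 0.42, 0.15, 0.03], size=n)
    flags = {f"flag_{c}": rng.binomial(1, p, n) for c, p in
             [("chf", 0.08), ("copd", 0.10), ("diabetes", 0.22),
              ("cancer", 0.12), ("delirium", 0.04)]}

    intervals = {
        "start_to_induction_min": rng.gamma(2.0, 7.5, n),
        "induction_to_incision_min": rng.gamma(2.0, 12.5, n),
        "incision_to_dressing_min": rng.gamma(1.8, 65.0, n),
        "dressing_to_emergence_min": rng.gamma(2.0, 5.0, n),
        "emergence_to_end_min": rng.gamma(2.0, 7.0, n),
    }
    intervals = {k: np.round(v, 1) for k, v in intervals.items()}
    anesthesia_duration = np.round(
        sum(intervals.values()) + rng.gamma(2.0, 4.0, n), 1)

    anesthesia_type = rng.choice(["general", "regional", "mac"],
                                 p=[0.72, 0.17, 0.11], size=n)
    block_flag = rng.binomial(1, 0.18, n)
    day_of_week = rng.integers(0, 7, n)
    day_type = np.where(day_of_week >= 5, "weekend", "weekday")
    admission_source = rng.choice(["home", "emergency", "transfer"],
                                  p=[0.62, 0.28, 0.10], size=n)

    # ---- provider assignments ----------------------------------------------
    prefixes = {"surgical_team": "SURG", "other_clinician": "CLIN",
                "nurse": "NURS", "technician": "TECH", "other": "MISC"}
    pools = {r: np.array([f"{prefixes[r]}{j:05d}" for j in
                          range(config.provider_pool_sizes[r])])
             for r in PROVIDER_ROLES}
    ranges = [config.role_count_ranges[r] for r in PROVIDER_ROLES]
    asg_enc, asg_prov, asg_role = [], [], []
    role_counts = np.zeros((n, len(PROVIDER_ROLES)), dtype=int)
    for i in range(n):
        counts = [rng.integers(a, b + 1) for a, b in ranges]
        for j, role in enumerate(PROVIDER_ROLES):
            c = min(counts[j], len(pools[role]))
            if c == 0:
                continue
            chosen = rng.choice(pools[role], size=c, replace=False)
            asg_enc.extend([enc_ids[i]] * c)
            asg_prov.extend(chosen.tolist())
            asg_role.extend([role] * c)
            role_counts[i, j] = c
    assignments = pd.DataFrame(
        {"encounter_id": asg_enc, "provider_id": asg_prov, "role": asg_role})

    # ---- pre-operative transfers -------------------------------------------
    unit_p = np.array([0.25, 0.15, 0.60])  # intermediate, intensive, acute
    unit_means = {"intermediate": 20.0, "intensive": 40.0, "acute": 30.0}
    n_stays = rng.poisson(config.transfer_rate, n)
    trf_enc, trf_unit, trf_seq, trf_dur = [], [], [], []
    stay_counts = np.zeros((n, len(CARE_UNITS)), dtype=int)
    unit_hours = np.zeros((n, len(CARE_UNITS)))
    for i in range(n):
        for k in range(n_stays[i]):
            u = rng.choice(len(CARE_UNITS), p=unit_p)
            d = round(float(rng.gamma(1.5, unit_means[CARE_UNITS[u]] / 1.5)), 2)
            trf_enc.append(enc_ids[i])
            trf_unit.append(CARE_UNITS[u])
            trf_seq.append(k)
            trf_dur.append(d)
            stay_counts[i, u] += 1
            unit_hours[i, u] += d
    transfers = pd.DataFrame({"encounter_id": trf_enc, "unit_type": trf_unit,
                              "sequence_index": trf_seq, "duration": trf_dur})

    # ---- planted outcomes ---------------------------------------------------
    covariates = {
        "age": age, "height": height, "weight": weight, "bmi": bmi,
        "cci": cci.astype(float), "asa_ps": asa_ps.astype(float),
        "anesthesia_duration_min": anesthesia_duration,
        **{k: v for k, v in intervals.items()},
        "preop_intermediate_hours": unit_hours[:, 0],
        "preop_intensive_hours": unit_hours[:, 1],
        "preop_acute_hours": unit_hours[:, 2],
    }
    connectivity = {
        **{f"n_assign_{r}": role_counts[:, j].astype(float)
           for j, r in enumerate(PROVIDER_ROLES)},
        "n_providers": role_counts.sum(axis=1).astype(float),
        "n_transfers": np.maximum(n_stays - 1, 0).astype(float),
        **{f"n_stays_{u}": stay_counts[:, j].astype(float)
           for j, u in enumerate(CARE_UNITS)},
        **{f"{u}_hours": unit_hours[:, j] for j, u in enumerate(CARE_UNITS)},
    }
    z_terms = {k: _standardize(v) for k, v in {**covariates, **connectivity}.items()}

    def _logits(outcome):
        total = np.full(n, float(config.baseline_logit[outcome]))
        for term, w in config.effect_weights.get(outcome, {}).items():
            total += w * z_terms[term]
        return total

    plos = rng.random(n) < expit(_logits("plos"))
    mort90 = rng.random(n) < expit(_logits("mort90"))
    is_mort30 = rng.random(n) < config.mort30_fraction

    thr = config.plos_threshold_days
    los_neg = np.round(thr * rng.beta(2.0, 1.6, n), 2)
    los_pos = np.round(thr + rng.gamma(1.5, 3.0, n) + 0.01, 2)
    postop_los = np.where(plos, los_pos, los_neg)

    death_offset = np.full(n, np.nan)
    d30 = rng.integers(1, 31, n)
    d90 = rng.integers(31, 91, n)
    death_offset[mort90 & is_mort30] = d30[mort90 & is_mort30]
    death_offset[mort90 & ~is_mort30] = d90[mort90 & ~is_mort30]

    encounters = pd.DataFrame({
        "encounter_id": enc_ids, "patient_id": patient_ids,
        "age": age, "sex": p_sex[rep], "race_ethnicity": p_race[rep],
        "marital_status": p_marital[rep], "height": height, "weight": weight,
        "bmi": bmi, "cci": cci, "asa_ps": asa_ps, **flags, **intervals,
        "anesthesia_duration_min": anesthesia_duration,
        "anesthesia_type": anesthesia_type, "block_flag": block_flag,
        "day_of_week": day_of_week, "day_type": day_type,
        "admission_source": admission_source,
        "preop_intermediate_hours": np.round(unit_hours[:, 0], 2),
        "preop_intensive_hours": np.round(unit_hours[:, 1], 2),
        "preop_acute_hours": np.round(unit_hours[:, 2], 2),
        "postop_los": postop_los, "death_offset": death_offset,
    })
    encounters = inject_missingness(encounters, config.missingness_rates,
                                    seed=int(rng.integers(0, 2**31 - 1)))
    return encounters, assignments, transfers


def inject_missingness(table: pd.DataFrame, rates: Mapping[str, float],
                       seed: int) -> pd.DataFrame:
    """MCAR-mask features of ``table`` at the given per-feature rates."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    for feat, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {feat!r} must lie in [0, 1], got {rate}")
        if feat not in out.columns:
            raise KeyError(f"feature {feat!r} not in table")
        mask = rng.random(len(out)) < rate
        if mask.any():
            col = out[feat]
            if not (pd.api.types.is_float_dtype(col) or col.dtype == object):
                out[feat] = col.astype(float)
            out.loc[mask, feat] = np.nan
    return out


def tables_to_csv(encounters, assignments, transfers, outdir) -> None:
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    encounters.to_csv(outdir / "encounters.csv", index=False)
    assignments.to_csv(outdir / "assignments.csv", index=False)
    transfers.to_csv(outdir / "transfers.csv", index=False)


def tables_from_csv(indir):
    from pathlib import Path
    indir = Path(indir)
    encounters = pd.read_csv(indir / "encounters.csv")
    assignments = pd.read_csv(indir / "assignments.csv")
    transfers = pd.read_csv(indir / "transfers.csv")
    return encounters, assignments, transfers


def tables_digest(*frames) -> str:
    """Stable content digest of a sequence of DataFrames (for manifests)."""
    import hashlib
    h = hashlib.sha256()
    for f in frames:
        buf = io.StringIO()
        f.to_csv(buf, index=False)
        h.update(buf.getvalue().encode())
    return h.hexdigest()
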