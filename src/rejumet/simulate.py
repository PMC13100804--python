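"""Synthetic study generators.

Two designs are emulated, mirroring the cross-species structure the pipeline
analyses:

* a cross-sectional mouse serum study with arms young WT, old WT ± losartan
  and old AT1/AT2 receptor-knockout ± losartan, where aging broadly
  *decreases* metabolite concentrations and losartan partially reverses the
  aging shift in a receptor-dependent way;
* a longitudinal human dose-escalation trial (0 → 25 → 50 → 100 mg across
  8-week visits, plus a placebo arm held at 0 mg) where aging effects are
  external per-year β coefficients, broadly *positive*, and the injected
  reversal magnitude follows a configurable polynomial in dose (by default a
  U-shape peaking at 50 mg).

Concentrations are generated on the log2 scale — class baseline + per-feature
offset + a shared per-sample class factor (class-structured covariance) +
design effects + Gaussian noise — then exponentiated, so "log2 fold change"
is the natural effect unit.  Values below a per-feature detection quantile
are recorded as missing, not zero.  Every generator is a pure function of its
config, including the seed.

Default magnitudes are chosen so that the emulated studies produce
signature-reversal correlations on the scale the real designs exhibit
(treatment-vs-aging Spearman ρ ≈ −0.3 at the mouse arm sizes, per-subject
ρ ≈ −0.2 at 25 mg in the human design); see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .datatypes import EffectVector, FeatureMatrix, METABOLITE_CLASSES

#: Default class mix approximating the composition of the 180-analyte
#: targeted panel (PC-dominated, with AA/AC/BA/LysoPC/SM and one hexose bin).
DEFAULT_CLASS_PROPORTIONS: Dict[str, float] = {
    "AA": 0.12, "AC": 0.21, "BA": 0.10, "LysoPC": 0.08,
    "PC": 0.40, "SM": 0.08, "H": 0.01,
}

#: Typical log2 concentration (µM) baselines per class.
_CLASS_BASELINE_LOG2 = {
    "AA": 6.0, "AC": 1.0, "BA": 0.5, "LysoPC": 4.0,
    "PC": 5.0, "SM": 4.5, "H": 12.0, "other": 3.0,
}


@dataclass
class GroundTruth:
    """The generator's injected truth, for parameter-recovery testing."""

    feature_ids: List[str]
    aging_effect_per_feature: np.ndarray
    treatment_effect_per_feature: np.ndarray
    reversed_feature_flags: np.ndarray
    subject_random_intercepts: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.feature_ids)
        for name in ("aging_effect_per_feature", "treatment_effect_per_feature",
                     "reversed_feature_flags"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length n_features={n}")
            setattr(self, name, arr)
        flagged = self.reversed_feature_flags.astype(bool)
        prod = (self.aging_effect_per_feature[flagged]
                * self.treatment_effect_per_feature[flagged])
        if np.any(prod > 0):
            raise ValueError("reversed features must satisfy sign(treatment) = -sign(aging)")

    def to_dict(self) -> dict:
        return {
            "feature_ids": list(self.feature_ids),
            "aging_effect_per_feature": self.aging_effect_per_feature.tolist(),
            "treatment_effect_per_feature": self.treatment_effect_per_feature.tolist(),
            "reversed_feature_flags": self.reversed_feature_flags.astype(bool).tolist(),
            "subject_random_intercepts": dict(self.subject_random_intercepts),
        }


def _check_fraction(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


def _check_proportions(props: Dict[str, float]) -> None:
    total = float(sum(props.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class_proportions must sum to 1, got {total}")
    unknown = set(props) - set(METABOLITE_CLASSES) - {"other"}
    if unknown:
        raise ValueError(f"unknown class labels in proportions: {sorted(unknown)}")


def allocate_class_counts(proportions: Dict[str, float], n_features: int) -> Dict[str, int]:
    """Deterministic largest-remainder apportionment of features to classes."""
    _check_proportions(proportions)
    labels = list(proportions)
    exact = np.array([proportions[c] * n_features for c in labels])
    counts = np.floor(exact).astype(int)
    remainder = n_features - int(counts.sum())
    # distribute leftovers by largest fractional part; ties broken by position
    order = np.argsort(-(exact - counts), kind="stable")
    for k in order[:remainder]:
        counts[k] += 1
    return dict(zip(labels, counts.tolist()))


def _make_features(proportions: Dict[str, float], n_features: int):
    counts = allocate_class_counts(proportions, n_features)
    feature_ids, classes = [], []
    for cls in counts:
        for i in range(counts[cls]):
            feature_ids.append(f"{cls}_{i + 1:03d}")
            classes.append(cls)
    annotation = pd.Series(classes, index=feature_ids)
    return feature_ids, annotation


@dataclass
class MouseDesignConfig:
    """Arm sizes and effect magnitudes of the cross-sectional mouse study.

    Defaults echo the reference design: young WT n=7, old WT control n=10,
    old WT losartan n=14, old AT1KO 8/5 (control/losartan), old AT2KO 7/6;
    120 quantifiable features.  Aging decreases ~60% of features by ~0.6 log2
    units on average; losartan reverses half of those at half strength in WT,
    attenuated ×0.5 in AT1KO and ×0 in AT2KO.
    """

    n_young_wt: int = 7
    n_old_wt_ctrl: int = 10
    n_old_wt_los: int = 14
    n_old_at1ko_ctrl: int = 8
    n_old_at1ko_los: int = 5
    n_old_at2ko_ctrl: int = 7
    n_old_at2ko_los: int = 6
    n_features: int = 120
    class_proportions: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    frac_age_affected: float = 0.6
    mean_aging_log2fc: float = -0.6
    aging_sd_log2fc: float = 0.3
    reversal_fraction: float = 0.5
    reversal_strength: float = 0.5
    noise_sd_log2: float = 0.3
    class_factor_sd_log2: float = 0.15
    lod_censor_rate: float = 0.02
    bodyweight_mean_sd: Tuple[float, float] = (30.0, 3.0)
    receptor_attenuation: Dict[str, float] = field(
        default_factory=lambda: {"WT": 1.0, "AT1KO": 0.5, "AT2KO": 0.0})
    seed: int = 0

    def validate(self) -> None:
        arms = self.arm_sizes()
        if any(n < 0 for n in arms.values()):
            raise ValueError("arm sizes must be non-negative")
        if sum(arms.values()) == 0:
            raise ValueError("empty design")
        _check_proportions(self.class_proportions)
        for name in ("frac_age_affected", "reversal_fraction", "reversal_strength",
                     "lod_censor_rate"):
            _check_fraction(getattr(self, name), name)
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be non-negative")

    def arm_sizes(self) -> Dict[str, int]:
        return {
            "young_WT": self.n_young_wt,
            "old_WT_ctrl": self.n_old_wt_ctrl,
            "old_WT_los": self.n_old_wt_los,
            "old_AT1KO_ctrl": self.n_old_at1ko_ctrl,
            "old_AT1KO_los": self.n_old_at1ko_los,
            "old_AT2KO_ctrl": self.n_old_at2ko_ctrl,
            "old_AT2KO_los": self.n_old_at2ko_los,
        }


_ARM_FIELDS = {
    "young_WT": ("young", "WT", "control"),
    "old_WT_ctrl": ("old", "WT", "control"),
    "old_WT_los": ("old", "WT", "losartan"),
    "old_AT1KO_ctrl": ("old", "AT1KO", "control"),
    "old_AT1KO_los": ("old", "AT1KO", "losartan"),
    "old_AT2KO_ctrl": ("old", "AT2KO", "control"),
    "old_AT2KO_los": ("old", "AT2KO", "losartan"),
}


def _feature_baselines(annotation: pd.Series, rng: np.random.Generator) -> np.ndarray:
    base = np.array([_CLASS_BASELINE_LOG2.get(c, 3.0) for c in annotation])
    return base + rng.normal(0.0, 1.0, size=len(annotation))


def _mouse_truth(config: MouseDesignConfig, feature_ids, rng) -> GroundTruth:
    n = config.n_features
    aging = np.zeros(n)
    n_affected = int(round(config.frac_age_affected * n))
    affected = rng.choice(n, size=n_affected, replace=False)
    draws = rng.normal(config.mean_aging_log2fc, config.aging_sd_log2fc, size=n_affected)
    draws[draws == 0.0] = config.mean_aging_log2fc  # keep affected effects non-zero
    aging[affected] = draws
    reversed_flags = np.zeros(n, dtype=bool)
    n_rev = int(round(config.reversal_fraction * n_affected))
    rev = rng.choice(affected, size=n_rev, replace=False)
    reversed_flags[rev] = True
    treatment = np.where(reversed_flags, -config.reversal_strength * aging, 0.0)
    return GroundTruth(list(feature_ids), aging, treatment, reversed_flags)


def _censor_below_lod(values: np.ndarray, rate: float) -> np.ndarray:
    """Mark the lowest `rate` fraction of each feature's values as missing."""
    if rate <= 0:
        return values
    out = values.copy()
    n = values.shape[0]
    k = int(np.floor(rate * n))
    if k == 0:
        return out
    order = np.argsort(values, axis=0, kind="stable")
    for j in range(values.shape[1]):
        out[order[:k, j], j] = np.nan
    return out


def generate_mouse_study(config: MouseDesignConfig):
    """Generate the mouse serum metabolome study.

    Returns ``(FeatureMatrix (natural scale), annotation, metadata, GroundTruth)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    feature_ids, annotation = _make_features(config.class_proportions, config.n_features)
    baselines = _feature_baselines(annotation, rng)
    truth = _mouse_truth(config, feature_ids, rng)

    class_labels = list(dict.fromkeys(annotation))
    class_index = np.array([class_labels.index(c) for c in annotation])

    rows, meta_rows = [], []
    counter = 0
    for arm, n_arm in config.arm_sizes().items():
        age_group, genotype, treatment = _ARM_FIELDS[arm]
        atten = config.receptor_attenuation.get(genotype, 1.0)
        for _ in range(n_arm):
            counter += 1
            sid = f"M{counter:03d}"
            class_factor = rng.normal(0.0, config.class_factor_sd_log2, size=len(class_labels))
            log2_vals = baselines + class_factor[class_index]
            if age_group == "old":
                log2_vals = log2_vals + truth.aging_effect_per_feature
            if treatment == "losartan":
                log2_vals = log2_vals + atten * truth.treatment_effect_per_feature
            log2_vals = log2_vals + rng.normal(0.0, config.noise_sd_log2,
                                               size=config.n_features)
            rows.append(log2_vals)
            meta_rows.append({
                "sample_id": sid, "subject_id": sid, "species": "mouse",
                "group": arm, "age_group": age_group, "genotype": genotype,
                "treatment": treatment,
                "body_weight_g": rng.normal(*config.bodyweight_mean_sd),
            })

    values = np.exp2(np.vstack(rows))
    values = _censor_below_lod(values, config.lod_censor_rate)
    sample_ids = [m["sample_id"] for m in meta_rows]
    matrix = FeatureMatrix(
        pd.DataFrame(values, index=sample_ids, columns=feature_ids), scale="natural")
    metadata = pd.DataFrame(meta_rows)
    return matrix, annotation, metadata, truth


@dataclass
class HumanDesignConfig:
    """Longitudinal dose-escalation design for the human trial.

    Treated subjects follow ``dose_schedule`` (visit index, dose in mg);
    placebo subjects sit at 0 mg throughout.  ``dose_response_shape`` gives
    (linear, quadratic) coefficients of the injected reversal magnitude
    r(dose); the default peaks at 50 mg with magnitude ≈ 10 "years reversed"
    (r(25)=7.5, r(50)=10, r(100)=0), matching a U-shaped score response.
    """

    n_placebo: int = 9
    n_treated: int = 7
    dose_schedule: Tuple[Tuple[int, int], ...] = ((0, 0), (1, 25), (2, 50), (3, 100))
    n_features: int = 160
    class_proportions: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    mean_aging_beta: float = 0.02
    aging_beta_sd: float = 0.015
    dose_response_shape: Tuple[float, float] = (0.4, -0.004)
    bmi_mean_sd: Tuple[float, float] = (27.0, 3.0)
    noise_sd_log2: float = 0.35
    subject_sd_log2: float = 0.3
    class_factor_sd_log2: float = 0.1
    seed: int = 0

    ALLOWED_DOSES = (0, 25, 50, 100)

    def validate(self) -> None:
        if self.n_placebo < 0 or self.n_treated < 0:
            raise ValueError("counts must be non-negative")
        if self.n_placebo + self.n_treated == 0:
            raise ValueError("empty design")
        visits = [v for v, _ in self.dose_schedule]
        if any(b <= a for a, b in zip(visits, visits[1:])):
            raise ValueError("dose_schedule must be strictly increasing in visit index")
        for _, dose in self.dose_schedule:
            if dose not in self.ALLOWED_DOSES:
                raise ValueError(f"dose {dose} not in allowed set {self.ALLOWED_DOSES}")
        if self.n_treated > 0 and (not self.dose_schedule
                                   or self.dose_schedule[0][1] != 0):
            raise ValueError("treated subjects have no baseline (dose 0) visit")
        _check_proportions(self.class_proportions)

    def reversal_magnitude(self, dose: float) -> float:
        lin, quad = self.dose_response_shape
        return lin * dose + quad * dose ** 2


def generate_human_study(config: HumanDesignConfig):
    """Generate the longitudinal human trial.

    Returns ``(FeatureMatrix (natural), annotation, metadata, GroundTruth)``;
    one row per subject-visit, within-subject correlation from a per-subject
    random intercept on the log2 scale.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    feature_ids, annotation = _make_features(config.class_proportions, config.n_features)
    baselines = _feature_baselines(annotation, rng)

    beta_age = rng.normal(config.mean_aging_beta, config.aging_beta_sd,
                          size=config.n_features)
    # treatment pushes each feature against its own aging direction
    treatment_unit = -beta_age
    flags = beta_age != 0
    truth = GroundTruth(list(feature_ids), beta_age, treatment_unit, flags)

    class_labels = list(dict.fromkeys(annotation))
    class_index = np.array([class_labels.index(c) for c in annotation])
    visit_indices = [v for v, _ in config.dose_schedule]

    subjects = ([(f"P{i + 1:03d}", "placebo") for i in range(config.n_placebo)]
                + [(f"T{i + 1:03d}", "losartan") for i in range(config.n_treated)])

    rows, meta_rows = [], []
    for subj, arm in subjects:
        intercept = rng.normal(0.0, config.subject_sd_log2)
        truth.subject_random_intercepts[subj] = float(intercept)
        bmi = rng.normal(*config.bmi_mean_sd)
        subj_offsets = baselines + intercept
        for visit, dose in config.dose_schedule:
            actual_dose = dose if arm == "losartan" else 0
            r = config.reversal_magnitude(actual_dose)
            class_factor = rng.normal(0.0, config.class_factor_sd_log2,
                                      size=len(class_labels))
            log2_vals = (subj_offsets + class_factor[class_index]
                         + r * treatment_unit
                         + rng.normal(0.0, config.noise_sd_log2, size=config.n_features))
            meta_rows.append({
                "sample_id": f"{subj}_v{visit}", "subject_id": subj,
                "species": "human", "treatment": arm, "dose_mg": actual_dose,
                "visit_index": visit, "bmi": bmi,
            })
            rows.append(log2_vals)

    values = np.exp2(np.vstack(rows))
    sample_ids = [m["sample_id"] for m in meta_rows]
    matrix = FeatureMatrix(
        pd.DataFrame(values, index=sample_ids, columns=feature_ids), scale="natural")
    return matrix, annotation, pd.DataFrame(meta_rows), truth


def generate_external_age_coefficients(truth: GroundTruth, error_sd: float,
                                       seed: int) -> EffectVector:
    """Noisy external per-year age coefficients (β-age) for the truth's features.

    Emulates importing an independently estimated aging model: β equals the
    generator's aging effect plus Normal(0, error_sd) estimation error, with
    nominal SE and two-sided normal p-values.
    """
    if error_sd < 0:
        raise ValueError("error_sd must be non-negative")
    rng = np.random.default_rng(seed)
    beta = truth.aging_effect_per_feature + rng.normal(0.0, error_sd,
                                                       size=len(truth.feature_ids))
    from scipy import stats

    if error_sd > 0:
        se = np.full_like(beta, error_sd)
        p = 2.0 * stats.norm.sf(np.abs(beta) / error_sd)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    else:
        se = np.zeros_like(beta)
        p = np.where(beta != 0, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {"estimate": beta, "se": se, "t": np.nan, "p": p, "q": np.nan},
        index=truth.feature_ids)
    return EffectVector(table, label="beta-age", n_used=len(beta))


def generate_survival_cohort(n_treated: int, n_control: int, hazard_treated: float,
                             hazard_control: float, followup_days: int,
                             seed: int) -> pd.DataFrame:
    """Exponential event times, administratively censored at ``followup_days``."""
    if n_treated < 0 or n_control < 0:
        raise ValueError("counts must be non-negative")
    if hazard_treated <= 0 or hazard_control <= 0:
        raise ValueError("hazard rates must be positive")
    if followup_days < 0:
        raise ValueError("followup_days must be non-negative")
    rng = np.random.default_rng(seed)
    records = []
    for group, n, hazard in (("losartan", n_treated, hazard_treated),
                             ("control", n_control, hazard_control)):
        times = rng.exponential(1.0 / hazard, size=n)
        for i, t in enumerate(times):
            event = int(t <= followup_days)
            records.append({
                "subject_id": f"{group[:3].upper()}{i + 1:03d}", "group": group,
                "time_days": float(min(t, followup_days)), "event": event,
            })
    return pd.DataFrame(records)


#: Physiologic baselines for the clinical metabolic panel (test-bed only):
#: sodium mmol/L, glucose mg/dL, blood urea nitrogen mg/dL.
CLINICAL_BASELINES = {"sodium": (140.0, 2.0), "glucose": (95.0, 10.0), "bun": (16.0, 4.0)}
#: Within-subject repeat-measurement noise SDs for the same analytes.
CLINICAL_VISIT_NOISE = {"sodium": 0.8, "glucose": 5.0, "bun": 1.5}


def generate_clinical_panel(metadata: pd.DataFrame, dose_effect_na: float,
                            seed: int,
                            dose_shape: Tuple[float, float] = (2.0, -0.02)) -> pd.DataFrame:
    """Clinical panel values (sodium/glucose/BUN) per sample.

    Sodium is shifted by ``dose_effect_na`` (mmol/L per mg-equivalent) times
    the configured dose shape r(d) = lin·d + quad·d²; with the default shape
    r peaks at 50 mg (r(50) = 50 mg-equivalents).
    """
    if "dose_mg" not in metadata.columns:
        raise ValueError("metadata must carry a dose_mg field")
    rng = np.random.default_rng(seed)
    subjects = list(dict.fromkeys(metadata["subject_id"]))
    base = {
        s: {k: rng.normal(*CLINICAL_BASELINES[k]) for k in CLINICAL_BASELINES}
        for s in subjects
    }
    lin, quad = dose_shape
    records = []
    for _, row in metadata.iterrows():
        b = base[row["subject_id"]]
        dose = float(row["dose_mg"])
        shift = dose_effect_na * (lin * dose + quad * dose ** 2)
        records.append({
            "sample_id": row["sample_id"],
            "sodium_mmol_l": b["sodium"] + shift
            + rng.normal(0.0, CLINICAL_VISIT_NOISE["sodium"]),
            "glucose_mg_dl": max(b["glucose"]
                                 + rng.normal(0.0, CLINICAL_VISIT_NOISE["glucose"]), 1.0),
            "bun_mg_dl": max(b["bun"]
                             + rng.normal(0.0, CLINICAL_VISIT_NOISE["bun"]), 1.0),
        })
    return pd.DataFrame(records)
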