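"""End-to-end orchestration of the cross-species rejuvenation analysis.

``run_pipeline`` drives every stage on synthetic data: generation of the
mouse and human studies, QC, per-feature moderated differential abundance,
signature-reversal scoring (group level and per subject), dose–response
mixed models, class-level models, cross-condition network/PCA integration,
survival and clinical-osmolality analyses, and a marker-set enrichment run.
All outputs are written as deterministic CSV/JSON under ``out_dir``; the
returned summary dict holds the headline statistics.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import io as rio
from .datatypes import EffectVector, FeatureMatrix
from .differential import ModeratedLinearModel, bh_adjust, build_design, fisher_combine
from .dose_response import (fit_class_dose_models, fit_mouse_class_model,
                            fit_random_intercept_lmm, select_polynomial_order)
from .enrichment import permutation_pvalues
from .integration import EffectPCA, build_effect_network
from .preprocess import class_sums, drop_flagged_samples, flag_outlier_samples, log2_transform
from .signature import (reversal_score, score_family, scores_to_frame,
                        subject_signature_scores, subject_scores_to_frame)
from .simulate import (HumanDesignConfig, MouseDesignConfig, generate_clinical_panel,
                       generate_external_age_coefficients, generate_human_study,
                       generate_mouse_study, generate_survival_cohort)
from .survival import calculated_osmolality, kaplan_meier

logger = logging.getLogger("rejumet")


def two_group_effect(matrix_log2: FeatureMatrix, meta: pd.DataFrame,
                     group_col: str, level, reference, label: str,
                     covariates=(), block: Optional[str] = None) -> EffectVector:
    """Moderated log2FC of ``level`` vs ``reference`` on the matching samples."""
    sub = meta[meta[group_col].isin([level, reference])].reset_index(drop=True)
    design = build_design(sub, group=group_col, covariates=covariates,
                          block=block, reference=reference)
    sub_matrix = matrix_log2.subset_samples(sub["sample_id"])
    model = ModeratedLinearModel().fit(design, sub_matrix)
    return model.contrast_effects(level, label=label)


def mouse_condition_effects(matrix_log2: FeatureMatrix,
                            meta: pd.DataFrame) -> Dict[str, EffectVector]:
    """The six mouse condition effects: aging vs young, all others vs old control."""
    effects = {}
    effects["mouse aging"] = two_group_effect(
        matrix_log2, meta, "group", "old_WT_ctrl", "young_WT", "mouse aging",
        covariates=("body_weight_g",))
    for arm, label in (("old_WT_los", "Los WT"), ("old_AT1KO_ctrl", "AT1KO"),
                       ("old_AT2KO_ctrl", "AT2KO"), ("old_AT1KO_los", "Los AT1KO"),
                       ("old_AT2KO_los", "Los AT2KO")):
        effects[label] = two_group_effect(
            matrix_log2, meta, "group", arm, "old_WT_ctrl", label,
            covariates=("body_weight_g",))
    return effects


def human_treatment_effects(matrix_log2: FeatureMatrix, meta: pd.DataFrame,
                            visit: int = 1) -> Dict[str, EffectVector]:
    """Follow-up vs baseline effects within each arm, subject-blocked."""
    effects = {}
    for arm, label in (("losartan", "human losartan"), ("placebo", "human placebo")):
        sub = meta[(meta["treatment"] == arm)
                   & (meta["visit_index"].isin([0, visit]))].reset_index(drop=True)
        if sub.empty:
            continue
        sub = sub.assign(phase=np.where(sub["visit_index"] == 0,
                                        "baseline", "followup"))
        design = build_design(sub, group="phase", block="subject_id",
                              reference="baseline")
        model = ModeratedLinearModel().fit(
            design, matrix_log2.subset_samples(sub["sample_id"]))
        effects[label] = model.contrast_effects("followup", label=label)
    return effects


def run_pipeline(config: dict, out_dir) -> dict:
    """Run every stage on the configured synthetic studies; returns the summary."""
    out = rio.ensure_dir(out_dir)
    seed = int(config.get("seed", 0))
    summary: dict = {"seed": seed}

    # ----- mouse study ---------------------------------------------------
    mouse_cfg = MouseDesignConfig(**{"seed": seed, **config.get("mouse", {})})
    m_matrix, m_ann, m_meta, m_truth = generate_mouse_study(mouse_cfg)
    rio.write_feature_matrix(m_matrix, out / "mouse_matrix.csv")
    rio.write_annotation(m_ann, out / "mouse_annotation.csv")
    rio.write_metadata(m_meta, out / "mouse_metadata.csv")
    rio.write_json(m_truth.to_dict(), out / "mouse_truth.json")

    m_log2 = log2_transform(m_matrix)
    m_qc = flag_outlier_samples(m_log2, threshold=config.get("qc_threshold", 3.0))
    m_qc.table.to_csv(out / "mouse_qc.csv", index=False,
                      float_format=rio.FLOAT_FORMAT)
    m_log2 = drop_flagged_samples(m_log2, m_qc)
    m_meta_kept = m_meta[~m_meta["sample_id"].isin(m_qc.flagged_samples)]

    effects = mouse_condition_effects(m_log2, m_meta_kept)
    for label, eff in effects.items():
        rio.write_effect_vector(eff, out / f"effect_{label.replace(' ', '_')}.csv")
    combined = fisher_combine(effects["mouse aging"].table["p"],
                              effects["Los WT"].table["p"])
    pd.DataFrame({
        "feature": effects["mouse aging"].feature_ids,
        "p_aging": effects["mouse aging"].table["p"].to_numpy(),
        "p_losartan": effects["Los WT"].table["p"].to_numpy(),
        "p_combined": combined, "q_combined": bh_adjust(combined),
    }).to_csv(out / "mouse_fisher_combined.csv", index=False,
              float_format=rio.FLOAT_FORMAT)

    family = score_family(effects["mouse aging"],
                          [effects[k] for k in ("Los WT", "Los AT1KO", "Los AT2KO",
                                                "AT1KO", "AT2KO")])
    forest = scores_to_frame(family)
    forest.to_csv(out / "mouse_signature_scores.csv", index=False,
                  float_format=rio.FLOAT_FORMAT)
    summary["mouse_reversal_rho"] = family[0].rho
    summary["mouse_reversal_p"] = family[0].p
    summary["mouse_los_at2ko_rho"] = family[2].rho

    m_class = class_sums(m_matrix.subset_samples(list(m_meta_kept["sample_id"])), m_ann)
    heat, _ = fit_mouse_class_model(m_class, m_meta_kept)
    heat.to_csv(out / "mouse_class_model.csv", index=False,
                float_format=rio.FLOAT_FORMAT)

    # ----- human study ---------------------------------------------------
    human_cfg = HumanDesignConfig(**{"seed": seed + 1, **config.get("human", {})})
    h_matrix, h_ann, h_meta, h_truth = generate_human_study(human_cfg)
    rio.write_feature_matrix(h_matrix, out / "human_matrix.csv")
    rio.write_annotation(h_ann, out / "human_annotation.csv")
    rio.write_metadata(h_meta, out / "human_metadata.csv")
    rio.write_json(h_truth.to_dict(), out / "human_truth.json")

    h_log2 = log2_transform(h_matrix)
    h_qc = flag_outlier_samples(h_log2, threshold=config.get("qc_threshold", 3.0))
    h_qc.table.to_csv(out / "human_qc.csv", index=False,
                      float_format=rio.FLOAT_FORMAT)
    h_log2 = drop_flagged_samples(h_log2, h_qc)
    h_meta_kept = h_meta[~h_meta["sample_id"].isin(h_qc.flagged_samples)]

    beta_age = generate_external_age_coefficients(
        h_truth, error_sd=config.get("beta_age_error_sd", 0.01), seed=seed + 2)
    rio.write_effect_vector(beta_age, out / "beta_age.csv")
    beta_age.label = "human aging"

    h_effects = human_treatment_effects(h_log2, h_meta_kept)
    for label, eff in h_effects.items():
        rio.write_effect_vector(eff, out / f"effect_{label.replace(' ', '_')}.csv")
    group_scores = score_family(beta_age, list(h_effects.values()))
    scores_to_frame(group_scores).to_csv(out / "human_group_scores.csv", index=False,
                                         float_format=rio.FLOAT_FORMAT)
    for s in group_scores:
        if s.label_y == "human losartan":
            summary["human_25mg_rho"] = s.rho
            summary["human_25mg_p"] = s.p

    series = subject_signature_scores(h_log2, h_meta_kept, beta_age)
    subject_scores = subject_scores_to_frame(series)
    subject_scores.to_csv(out / "human_subject_scores.csv", index=False,
                          float_format=rio.FLOAT_FORMAT)
    scored = subject_scores[np.isfinite(subject_scores["rho"])]
    by_dose = scored.groupby("dose_mg")["rho"].mean()
    summary["subject_rho_by_dose"] = {f"{int(d)}": float(v)
                                      for d, v in by_dose.items()}

    order, fits = select_polynomial_order(
        scored["rho"], scored["dose_mg"], scored["subject_id"],
        orders=config.get("dose_orders", (1, 2, 3)))
    rio.write_json({
        "selected_order": order,
        "fits": {str(o): {
            "fixed_effects": f.fixed_effects.to_dict("index"),
            "deviance": f.deviance, "aic": f.aic, "bic": f.bic,
            "sigma2_subject": f.random_intercept_variance,
            "sigma2_resid": f.residual_variance,
        } for o, f in fits.items()},
    }, out / "dose_model.json")
    summary["selected_polynomial_order"] = order
    best = fits[order]
    if "dose^2" in best.fixed_effects.index:
        summary["dose_quadratic_coef"] = float(
            best.fixed_effects.loc["dose^2", "estimate"])

    h_class = class_sums(h_matrix.subset_samples(list(h_meta_kept["sample_id"])), h_ann)
    class_table, _ = fit_class_dose_models(h_class, h_meta_kept, covariate="bmi")
    class_table.to_csv(out / "human_class_dose_models.csv", index=False,
                       float_format=rio.FLOAT_FORMAT)

    # ----- integration ---------------------------------------------------
    conditions = [effects[k] for k in ("mouse aging", "Los WT", "AT1KO", "AT2KO",
                                       "Los AT1KO", "Los AT2KO")]
    conditions += [beta_age, h_effects["human losartan"]]
    network = build_effect_network(conditions)
    network.edges.to_csv(out / "network_edges.csv", index=False,
                         float_format=rio.FLOAT_FORMAT)
    rio.write_json({"layout": {k: list(v) for k, v in network.layout.items()}},
                   out / "network_layout.json")
    aging_edge = network.edges[
        ((network.edges["node_a"] == "mouse aging")
         & (network.edges["node_b"] == "human aging"))
        | ((network.edges["node_a"] == "human aging")
           & (network.edges["node_b"] == "mouse aging"))]
    if len(aging_edge):
        summary["cross_species_aging_rho"] = float(aging_edge["rho"].iloc[0])

    pca = EffectPCA().fit(conditions)
    pd.DataFrame(pca.scores_, index=pca.condition_labels_).to_csv(
        out / "pca_scores.csv", float_format=rio.FLOAT_FORMAT)
    pd.DataFrame(pca.loadings_, index=pca.feature_ids_).to_csv(
        out / "pca_loadings.csv", float_format=rio.FLOAT_FORMAT)
    pd.DataFrame({"component": np.arange(1, len(pca.variance_fraction_) + 1),
                  "variance_fraction": pca.variance_fraction_}).to_csv(
        out / "pca_variance.csv", index=False, float_format=rio.FLOAT_FORMAT)
    summary["pc1_variance_pct"] = float(100.0 * pca.variance_fraction_[0])

    # ----- survival and clinical panel -----------------------------------
    surv_cfg = {"n_treated": 19, "n_control": 14, "hazard_treated": 0.006,
                "hazard_control": 0.02, "followup_days": 60,
                **config.get("survival", {})}
    cohort = generate_survival_cohort(seed=seed + 3, **surv_cfg)
    cohort.to_csv(out / "survival_cohort.csv", index=False,
                  float_format=rio.FLOAT_FORMAT)
    km = kaplan_meier(cohort)
    curves = []
    for group, curve in km.curves.items():
        c = curve.copy()
        c.insert(0, "group", group)
        curves.append(c)
    pd.concat(curves, ignore_index=True).to_csv(
        out / "survival_curves.csv", index=False, float_format=rio.FLOAT_FORMAT)
    rio.write_json({"chi_square": km.chi_square, "df": km.df, "p": km.p},
                   out / "logrank.json")
    summary["logrank_p"] = km.p

    panel = generate_clinical_panel(
        h_meta_kept, dose_effect_na=config.get("clinical", {}).get("dose_effect_na", 0.04),
        seed=seed + 4)
    panel = panel.assign(osmolality_mosm_kg=calculated_osmolality(
        panel["sodium_mmol_l"], panel["glucose_mg_dl"], panel["bun_mg_dl"]))
    panel.to_csv(out / "clinical_panel.csv", index=False,
                 float_format=rio.FLOAT_FORMAT)
    merged = panel.merge(h_meta_kept, on="sample_id")
    osmo_fit = fit_random_intercept_lmm(
        merged["osmolality_mosm_kg"], merged["dose_mg"], merged["subject_id"],
        order=2, covariates=pd.DataFrame({"bmi": merged["bmi"]}),
        outcome_name="calculated osmolality")
    rio.write_json({"fixed_effects": osmo_fit.fixed_effects.to_dict("index"),
                    "deviance": osmo_fit.deviance}, out / "osmolality_model.json")
    summary["osmolality_dose_quadratic_coef"] = float(
        osmo_fit.fixed_effects.loc["dose^2", "estimate"])

    # ----- marker-set enrichment ----------------------------------------
    los_t = effects["Los WT"].table["t"].dropna()
    marker_sets = {f"class_{cls}": tuple(m_ann.index[m_ann == cls])
                   for cls in dict.fromkeys(m_ann)}
    gsea = permutation_pvalues(los_t, marker_sets,
                               n_perm=int(config.get("enrichment", {}).get("n_perm", 200)),
                               seed=seed + 5)
    gsea.to_csv(out / "enrichment.csv", index=False, float_format=rio.FLOAT_FORMAT)

    rio.write_json(summary, out / "summary.json")
    return summary
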