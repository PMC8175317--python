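"""End-to-end per-tracer analysis and diagnostic-performance reporting.

For every tracer cohort and diagnostic contrast (AD vs CU, AD vs non-AD)
the pipeline computes, for each of the four theory-driven composite ROIs
and a contrast-specific data-driven ROI:

* AUC with a DeLong 95% CI (on the full contrast groups),
* the Youden cut-point with stratified-bootstrap 95% CIs, together with
  sensitivity/specificity (percent) at that cut,
* a paired DeLong test between the best-performing theory-driven ROI
  (highest point AUC) and the data-driven composite,

plus a cross-tracer summary giving, per ROI and contrast, the arithmetic
mean of the per-tracer cut-points (the "common threshold" statistic).

Cut-points are derived on AD vs amyloid-negative CU by default for the CU
contrast; ``cutpoint_scope="ad_vs_abneg_cu"`` re-uses that reference cut
for every contrast, while the default ``"per_contrast"`` re-derives the
cut against each contrast's own comparison group (non-AD for AD vs non-AD).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, default_atlas
from .features import cluster_features, cv_feature_importance, select_representatives
from .rois import CompositeROIDefinition, build_roi_table, builtin_rois
from .roc import auc, bootstrap_cis, delong_ci, delong_paired

logger = logging.getLogger("tauroi")

CONTRASTS = ("AD_vs_CU", "AD_vs_nonAD")
CUTPOINT_SCOPES = ("per_contrast", "ad_vs_abneg_cu")

SUBSET_FILTERS = ("excl_pd_no_dementia", "excl_abeta_pos_pd_dlb")


def apply_subset_filter(cohort: pd.DataFrame, filter_name: str) -> pd.DataFrame:
    """Sensitivity-analysis cohort filters.

    ``excl_pd_no_dementia``   — drop Parkinson's disease without dementia
    (subtype ``PD``; ``PDD`` retained).
    ``excl_abeta_pos_pd_dlb`` — drop amyloid-positive PD/PDD and DLB cases.
    """
    if filter_name == "excl_pd_no_dementia":
        drop = cohort["subtype"].eq("PD")
    elif filter_name == "excl_abeta_pos_pd_dlb":
        drop = cohort["subtype"].isin(["PD", "PDD", "DLB"]) & cohort[
            "abeta_status"
        ].eq("pos")
    else:
        raise KeyError(
            f"unknown subset filter {filter_name!r}; choose from {SUBSET_FILTERS}"
        )
    n_removed = int(drop.sum())
    logger.info("subset filter %s removed %d rows", filter_name, n_removed)
    return cohort.loc[~drop].reset_index(drop=True)


def summarize_cutpoints(cutpoints) -> float:
    """Cross-tracer common threshold: arithmetic mean of per-tracer cut-points."""
    values = np.asarray(list(cutpoints), dtype=float)
    if values.size == 0:
        raise ValueError("no cut-points to summarize")
    return float(values.mean())


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration for :func:`run_full_analysis`.

    ``cohorts`` maps tracer name to a wide cohort table (as produced by
    :func:`tauroi.generate_cohort` or :func:`tauroi.load_cohort`).
    """

    cohorts: dict[str, pd.DataFrame]
    contrasts: tuple[str, ...] = CONTRASTS
    atlas: RegionAtlas = field(default_factory=default_atlas)
    weighting: str = "volume_weighted"
    cutpoint_scope: str = "per_contrast"
    subset_filter: str | None = None
    bootstrap_B: int = 2000
    seed: int = 0
    data_driven: bool = True
    dd_kmax: int = 8
    dd_folds: int = 10
    dd_trees: int = 500

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("need at least one tracer cohort")
        if not self.contrasts:
            raise ValueError("need at least one contrast")
        unknown = set(self.contrasts) - set(CONTRASTS)
        if unknown:
            raise ValueError(f"unknown contrasts {sorted(unknown)}")
        if self.cutpoint_scope not in CUTPOINT_SCOPES:
            raise ValueError(f"cutpoint_scope must be one of {CUTPOINT_SCOPES}")


@dataclass(frozen=True)
class DiagnosticReport:
    """Structured result of the full analysis: one row per tracer/contrast/ROI."""

    rows: tuple[dict, ...]
    delong_comparisons: tuple[dict, ...]
    cross_tracer: dict
    selection_traces: dict
    meta: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.rows))

    def to_json(self) -> str:
        payload = {
            "meta": self.meta,
            "rows": list(self.rows),
            "delong_comparisons": list(self.delong_comparisons),
            "cross_tracer": self.cross_tracer,
            "selection_traces": self.selection_traces,
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    def save(self, json_path=None, csv_path=None) -> None:
        if json_path is not None:
            with open(json_path, "w", encoding="utf-8") as fh:
                fh.write(self.to_json())
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index=False, float_format="%.6g")

    def row(self, tracer: str, contrast: str, roi: str) -> dict:
        for r in self.rows:
            if (r["tracer"], r["contrast"], r["roi"]) == (tracer, contrast, roi):
                return r
        raise KeyError(f"no report row for {(tracer, contrast, roi)}")


def _contrast_groups(roi_table: pd.DataFrame, contrast: str):
    pos = roi_table[roi_table["diagnosis"].eq("AD")]
    neg_dx = "CU" if contrast == "AD_vs_CU" else "nonAD"
    neg = roi_table[roi_table["diagnosis"].eq(neg_dx)]
    return neg, pos


def _cut_reference_groups(roi_table: pd.DataFrame, contrast: str, scope: str):
    """Groups on which the Youden cut-point is derived."""
    pos = roi_table[roi_table["diagnosis"].eq("AD")]
    if scope == "ad_vs_abneg_cu" or contrast == "AD_vs_CU":
        neg = roi_table[
            roi_table["diagnosis"].eq("CU") & roi_table["abeta_status"].eq("neg")
        ]
    else:
        neg = roi_table[roi_table["diagnosis"].eq("nonAD")]
    return neg, pos


def _derive_data_driven(
    cohort: pd.DataFrame,
    contrast: str,
    config: AnalysisConfig,
    seed: int,
):
    labels = list(config.atlas.labels)
    neg, pos = _contrast_groups(cohort, contrast)
    frame = pd.concat([neg, pos], axis=0, ignore_index=True)
    X = frame[[f"suvr_{lab}" for lab in labels]].to_numpy(dtype=float)
    y = frame["diagnosis"].eq("AD").to_numpy(dtype=int)
    importance = cv_feature_importance(
        X, y, labels, n_folds=config.dd_folds, n_trees=config.dd_trees, seed=seed
    )
    dendrogram = cluster_features(X, labels)
    trace = select_representatives(
        dendrogram,
        importance,
        X,
        y,
        K_max=config.dd_kmax,
        n_folds=config.dd_folds,
        seed=seed,
    )
    return trace


def _roi_row(
    name: str,
    roi_table: pd.DataFrame,
    contrast: str,
    config: AnalysisConfig,
    seed: int,
) -> dict | None:
    neg, pos = _contrast_groups(roi_table, contrast)
    if neg.empty or pos.empty:
        logger.warning(
            "contrast %s skipped for ROI %s: empty comparison group", contrast, name
        )
        return None
    roc = delong_ci(neg[name].to_numpy(), pos[name].to_numpy())
    cut_neg, cut_pos = _cut_reference_groups(roi_table, contrast, config.cutpoint_scope)
    cut = bootstrap_cis(
        cut_neg[name].to_numpy(),
        cut_pos[name].to_numpy(),
        B=config.bootstrap_B,
        seed=seed,
    )
    return {
        "roi": name,
        "contrast": contrast,
        "auc": roc.auc,
        "auc_ci_low": roc.ci_low,
        "auc_ci_high": roc.ci_high,
        "cutpoint": cut.cutpoint,
        "cut_ci_low": cut.cut_ci[0],
        "cut_ci_high": cut.cut_ci[1],
        "sensitivity": cut.sensitivity,
        "sens_ci_low": cut.sens_ci[0],
        "sens_ci_high": cut.sens_ci[1],
        "specificity": cut.specificity,
        "spec_ci_low": cut.spec_ci[0],
        "spec_ci_high": cut.spec_ci[1],
        "youden_j": cut.youden_j,
        "n_neg": roc.n_neg,
        "n_pos": roc.n_pos,
    }


def run_full_analysis(config: AnalysisConfig) -> DiagnosticReport:
    """Run the complete multi-tracer analysis and assemble the report."""
    rows: list[dict] = []
    delong_rows: list[dict] = []
    traces: dict = {}
    filter_counts: dict = {}

    for t_idx, (tracer, cohort) in enumerate(sorted(config.cohorts.items())):
        if config.subset_filter is not None:
            before = len(cohort)
            cohort = apply_subset_filter(cohort, config.subset_filter)
            filter_counts[tracer] = before - len(cohort)
        theory_rois = builtin_rois(config.atlas, weighting=config.weighting)
        roi_table = build_roi_table(cohort, theory_rois)

        for c_idx, contrast in enumerate(config.contrasts):
            seed = int(config.seed + 1009 * t_idx + 101 * c_idx) % (2**31 - 1)
            contrast_rows: list[dict] = []
            for roi in theory_rois:
                row = _roi_row(roi.name, roi_table, contrast, config, seed)
                if row is None:
                    continue
                row.update({"tracer": tracer, "kind": "theory"})
                contrast_rows.append(row)
            if not contrast_rows:
                continue

            dd_members: tuple[str, ...] | None = None
            if config.data_driven:
                trace = _derive_data_driven(cohort, contrast, config, seed)
                dd_members = trace.final_members
                traces[f"{tracer}/{contrast}"] = {
                    "ks": list(trace.ks),
                    "selected": [list(s) for s in trace.selected],
                    "scores": list(trace.scores),
                    "chosen_k": trace.chosen_k,
                    "final_members": list(dd_members),
                }
                dd_roi = CompositeROIDefinition(
                    "data_driven", dd_members, weighting="unweighted"
                )
                dd_table = build_roi_table(cohort, [dd_roi])
                row = _roi_row("data_driven", dd_table, contrast, config, seed)
                if row is not None:
                    row.update(
                        {"tracer": tracer, "kind": "data_driven",
                         "members": list(dd_members)}
                    )
                    contrast_rows.append(row)

            rows.extend(contrast_rows)

            if config.data_driven and dd_members is not None:
                theory_only = [r for r in contrast_rows if r["kind"] == "theory"]
                best = max(theory_only, key=lambda r: r["auc"])
                neg, pos = _contrast_groups(roi_table, contrast)
                frame = pd.concat([neg, pos], axis=0, ignore_index=True)
                dd_frame = build_roi_table(
                    pd.concat(
                        _contrast_groups(cohort, contrast), axis=0, ignore_index=True
                    ),
                    [CompositeROIDefinition("data_driven", dd_members, "unweighted")],
                )
                res = delong_paired(
                    frame[best["roi"]].to_numpy(),
                    dd_frame["data_driven"].to_numpy(),
                    frame["diagnosis"].eq("AD").to_numpy(),
                )
                delong_rows.append(
                    {
                        "tracer": tracer,
                        "contrast": contrast,
                        "best_theory_roi": best["roi"],
                        "auc_theory": res.auc_a,
                        "auc_data_driven": res.auc_b,
                        "delta": res.delta,
                        "z": res.z,
                        "p": res.p,
                    }
                )

    cross: dict = {}
    for contrast in config.contrasts:
        per_roi: dict = {}
        roi_names = sorted({r["roi"] for r in rows if r["contrast"] == contrast})
        for name in roi_names:
            cuts = {
                r["tracer"]: r["cutpoint"]
                for r in rows
                if r["contrast"] == contrast and r["roi"] == name
            }
            per_roi[name] = {
                "per_tracer": cuts,
                "mean_cutpoint": summarize_cutpoints(cuts.values()),
            }
        cross[contrast] = per_roi

    meta = {
        "seed": config.seed,
        "bootstrap_B": config.bootstrap_B,
        "weighting": config.weighting,
        "cutpoint_scope": config.cutpoint_scope,
        "subset_filter": config.subset_filter,
        "subset_filter_removed": filter_counts,
        "tracers": sorted(config.cohorts),
        "contrasts": list(config.contrasts),
    }
    return DiagnosticReport(
        rows=tuple(rows),
        delong_comparisons=tuple(delong_rows),
        cross_tracer=cross,
        selection_traces=traces,
        meta=meta,
    )
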