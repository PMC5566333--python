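"""End-to-end orchestration: simulate/load -> error control -> quantification
-> dilution metrics -> reproducibility -> similarity -> report."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dilution as dil
from . import fdr, io, quant, repro, similarity
from .config import PipelineConfig
from .design import StudyDesign, build_design
from .simulate import StudyDataset, make_site_profiles, simulate_study

__all__ = ["run_pipeline", "score_and_filter", "StudyReport"]

log = logging.getLogger("swathbench")


@dataclass
class StudyReport:
    """Aggregated numbers from every stage, JSON-serialisable."""

    sections: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps({"provenance": self.provenance, **self.sections}, default=_jsonify, **kwargs)

    def summary_text(self) -> str:
        lines = ["swathbench study report", "=" * 24]
        for name, sec in self.sections.items():
            lines.append(f"\n[{name}]")
            if isinstance(sec, dict):
                for k, v in sec.items():
                    lines.append(f"  {k}: {_fmt(v)}")
            else:
                lines.append(f"  {_fmt(sec)}")
        return "\n".join(lines)


def _fmt(v):
    if isinstance(v, float):
        return f"{v:.4g}"
    return v


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def score_and_filter(
    records: pd.DataFrame,
    alpha: float = 0.01,
    lam: float = 0.4,
    subsample_ratio: float = 1.0,
    n_iterations: int = 5,
    seed: int = 0,
):
    """Discriminant scoring, q-values in both contexts, consecutive filter.

    Returns (scored records, q-tables dict, DetectionMatrix).
    """
    weights, d = fdr.learn_discriminant(
        records, subsample_ratio=subsample_ratio, n_iterations=n_iterations, seed=seed
    )
    scored = records.assign(d_score=d)
    tables = {
        "global_peptide": fdr.estimate_qvalues(scored, lam, fdr.GLOBAL, "peptide"),
        "global_protein": fdr.estimate_qvalues(scored, lam, fdr.GLOBAL, "protein"),
        "runwise_peptide": fdr.estimate_qvalues(scored, lam, fdr.EXPERIMENT_WIDE, "peptide"),
    }
    detection = fdr.consecutive_filter(
        tables["global_peptide"],
        tables["global_protein"],
        tables["runwise_peptide"],
        alpha=alpha,
        records=scored,
    )
    detection.provenance["weights"] = weights.tolist()
    return scored, tables, detection


def _detected_peakgroups(scored: pd.DataFrame, detection: fdr.DetectionMatrix) -> pd.DataFrame:
    """Target peak groups whose query passed the consecutive filter in that run."""
    calls = (
        detection.peptide.reset_index()
        .melt(id_vars="peptide_query_id", var_name="run_id", value_name="_det")
    )
    calls = calls[calls["_det"]]
    out = scored.merge(calls[["peptide_query_id", "run_id"]], on=["peptide_query_id", "run_id"], how="inner")
    return out


def run_pipeline(config: PipelineConfig, mode: str = "synthetic", out_dir: str | Path | None = None) -> StudyReport:
    """Execute the full benchmarking analysis and assemble the report.

    Synthetic mode generates the study from the config's generator knobs;
    real mode reads peak-group and SIS tables from the configured paths.
    Both the aggregated (all sites pooled before FDR control) and the
    site-by-site detection analyses are produced.
    """
    t0 = time.time()
    out_dir = Path(out_dir or config.out_dir) if (out_dir or config.out_dir) else None
    prov = {"config_hash": io.config_hash(config.to_dict()), "seed": config.seed, "mode": mode}
    report = StudyReport(provenance=prov)

    # ------------------------------------------------------------------ data
    stage = "simulate" if mode == "synthetic" else "load"
    try:
        if mode == "synthetic":
            design = build_design(n_sites=config.n_sites)
            profiles = make_site_profiles(design, config.seed, offset_range=config.offset_range)
            ds = simulate_study(
                design,
                profiles,
                seed=config.seed,
                dropout=config.dropout,
                n_proteins=config.n_proteins,
                mean_peptides=config.mean_peptides,
                span_orders=config.span_orders,
                absent_fraction=config.absent_fraction,
            )
        elif mode == "real":
            if not (config.input_peakgroups and config.input_sis):
                raise FileNotFoundError("real mode needs input_peakgroups and input_sis paths")
            design = build_design(n_sites=config.n_sites)
            pg = io.read_peakgroups(config.input_peakgroups)
            sis = io.read_sis(config.input_sis)
            runs = (
                sis[["run_id", "site_id", "day", "sample_id", "replicate_index"]]
                .drop_duplicates("run_id")
                .assign(acquisition_order=lambda d: range(1, len(d) + 1))
            )
            ds = StudyDataset(design=design, runs=runs, peakgroups=pg, sis=sis, truth=pd.DataFrame(), profiles={})
        else:
            raise ValueError(f"unknown mode {mode!r}")
        log.info("stage=%s runs=%d peakgroups=%d elapsed=%.1fs", stage, len(ds.runs), len(ds.peakgroups), time.time() - t0)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    run_order = ds.runs.sort_values(["site_id", "acquisition_order"])["run_id"].tolist()

    # --------------------------------------------------------- error control
    stage = "detect"
    try:
        scored, qtables, detection = score_and_filter(
            ds.peakgroups, config.alpha, config.lam, config.subsample_ratio, config.n_iterations, config.seed
        )
        curve_protein = fdr.cumulative_detection_curve(detection.protein, run_order)
        # contrast: run-context-only peptide filter, no global filtering
        rw = qtables["runwise_peptide"]
        rw_only = rw[(~rw["decoy"]) & (rw["q"] <= config.alpha)]
        rw_mat = (
            rw_only.assign(v=True)
            .pivot_table(index="unit_id", columns="run_id", values="v", aggfunc="any", fill_value=False)
            .reindex(columns=run_order, fill_value=False)
            .astype(bool)
        )
        curve_runonly = fdr.cumulative_detection_curve(rw_mat, run_order)

        per_site_counts = {}
        for site, site_runs in ds.runs.groupby("site_id"):
            site_records = ds.peakgroups[ds.peakgroups["run_id"].isin(site_runs["run_id"])]
            _, _, site_det = score_and_filter(
                site_records, config.alpha, config.lam, min(1.0, config.subsample_ratio * len(ds.runs) / len(site_runs)),
                config.n_iterations, config.seed,
            )
            per_site_counts[site] = int(len(site_det.protein))
        agg_per_site = {
            site: int(detection.protein[list(site_runs["run_id"])].any(axis=1).sum())
            for site, site_runs in ds.runs.groupby("site_id")
        }
        report.sections["detection"] = {
            "n_proteins_global": int(len(detection.protein)),
            "n_peptide_queries_global": int(len(detection.peptide)),
            "median_proteins_per_run": float(detection.protein.sum(axis=0).median()),
            "cumulative_protein_curve": curve_protein,
            "cumulative_runonly_peptide_curve": curve_runonly,
            "site_by_site_protein_counts": per_site_counts,
            "aggregated_per_site_protein_counts": agg_per_site,
        }
        log.info("stage=detect proteins=%d elapsed=%.1fs", len(detection.protein), time.time() - t0)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --------------------------------------------------------- quantification
    stage = "quantify"
    try:
        detected = _detected_peakgroups(scored, detection)
        coefs = quant.compute_normalization(detected)
        matrix = quant.infer_protein_abundance(detected)
        matrix_norm = quant.apply_normalization(matrix, coefs)
        log2m = quant.log2_matrix(matrix_norm)
        complete_units = repro.completeness(matrix, config.completeness_threshold)
        report.sections["quantification"] = {
            "n_proteins_quantified": int(len(matrix)),
            "n_complete_proteins": int(len(complete_units)),
            "normalization_reference": coefs.reference,
            "coefficient_range": (float(coefs.coefficients.min()), float(coefs.coefficients.max())),
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --------------------------------------------------------------- dilution
    stage = "dilution"
    try:
        sis_norm = quant.apply_normalization(ds.sis, coefs, run_column="run_id", value_columns=["area"])
        lloq_results = []
        for ms_level in ("MS2", "MS1"):
            for curve in dil.build_response_curves(ds.sis, ms_level):
                lloq_results.append(
                    dil.determine_lloq(curve, config.cv_max, config.sn_min, config.accuracy_band)
                )
        lloqs = dil.lloq_table(lloq_results)
        ms2 = lloqs[lloqs["ms_level"] == "MS2"]
        curves_ms2 = dil.build_response_curves(ds.sis, "MS2")
        folds = dil.step_fold_changes(
            curves_ms2,
            {(r.peptide_id, r.site_id): (None if np.isnan(r.lloq_fmol) else r.lloq_fmol) for r in ms2.itertuples()},
        )
        pct = dil.percent_detected(lloq_results, ds.design)
        avg_raw = dil.averaged_response_curve(curves_ms2, ds.design)
        avg_norm = dil.averaged_response_curve(dil.build_response_curves(sis_norm, "MS2"), ds.design)
        report.sections["dilution"] = {
            "median_lloq_fmol_ms2": float(ms2["lloq_fmol"].median()),
            "mean_dynamic_range_orders_ms2": float(ms2["dynamic_range_orders"].mean()),
            "mean_r_squared_ms2": float(ms2["r_squared"].mean()),
            **folds,
        }
        dilution_tables = {"lloq": lloqs, "percent_detected": pct, "avg_curve_raw": avg_raw, "avg_curve_norm": avg_norm}
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---------------------------------------------------------------- repro
    stage = "qc"
    try:
        cv_section = {}
        for normalized, sis_tab in ((False, ds.sis), (True, sis_norm)):
            for level in (repro.INTRA_DAY, repro.INTER_DAY, repro.INTER_SITE):
                rep = repro.cv_breakdown(sis_tab, level, scope="sis", normalized=normalized)
                tag = f"sis_{level}{'_norm' if normalized else ''}"
                cv_section[tag] = {"median": rep.median, "sd": rep.sd}
        mat_runs = ds.runs
        for level in (repro.INTRA_DAY, repro.INTER_DAY, repro.INTER_SITE):
            rep = repro.cv_breakdown(
                matrix_norm, level, scope="protein", normalized=True,
                runs=mat_runs, completeness_threshold=config.completeness_threshold,
            )
            cv_section[f"protein_{level}_norm"] = {"median": rep.median, "sd": rep.sd}
        pairs_ws = repro.repeatability_summary(detection.protein, ds.runs, "within-site")
        pairs_sw = repro.repeatability_summary(detection.protein, grouping="study-wide")
        pairs_ws_pep = repro.repeatability_summary(detection.peptide, ds.runs, "within-site")
        pairs_sw_pep = repro.repeatability_summary(detection.peptide, grouping="study-wide")
        report.sections["reproducibility"] = {
            "cv": cv_section,
            "repeatability_within_site_protein": repro.repeatability_medians(pairs_ws)["median_percent"].agg(["min", "max"]).tolist(),
            "repeatability_study_wide_protein": float(pairs_sw["percent"].median()),
            "repeatability_within_site_peptide": repro.repeatability_medians(pairs_ws_pep)["median_percent"].agg(["min", "max"]).tolist(),
            "repeatability_study_wide_peptide": float(pairs_sw_pep["percent"].median()),
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ------------------------------------------------------------- similarity
    stage = "similarity"
    try:
        corr = similarity.pearson_matrix(log2m)
        site_of = ds.runs.set_index("run_id")["site_id"]
        sim = similarity.similarity_summary(corr, site_of)
        dend = similarity.hierarchical_cluster(log2m)
        cut = dend.cut(len(ds.runs["site_id"].unique()))
        purity = similarity.cluster_purity(cut, site_of)
        report.sections["similarity"] = {**sim, "site_cluster_purity": float(purity)}
        newick = dend.to_newick()
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    report.provenance["elapsed_s"] = round(time.time() - t0, 1)

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        file_prov = {"config_hash": prov["config_hash"], "seed": prov["seed"]}
        io.write_peakgroups(ds.peakgroups, out_dir / "peakgroups.tsv", file_prov)
        io.write_sis(ds.sis, out_dir / "sis_areas.tsv", file_prov)
        if len(ds.truth):
            io.write_table(ds.truth, out_dir / "ground_truth.tsv", file_prov)
        for name, tab in qtables.items():
            io.write_table(tab, out_dir / f"qvalues_{name}.tsv", file_prov)
        io.write_matrix(detection.protein.astype(int), out_dir / "detection_protein.tsv", file_prov)
        io.write_matrix(detection.peptide.astype(int), out_dir / "detection_peptide.tsv", file_prov)
        io.write_matrix(matrix, out_dir / "protein_matrix.tsv", file_prov)
        io.write_matrix(matrix_norm, out_dir / "protein_matrix_normalized.tsv", file_prov)
        io.write_table(coefs.coefficients.rename("coefficient").reset_index(), out_dir / "normalization.tsv", file_prov)
        for name, tab in dilution_tables.items():
            io.write_table(tab, out_dir / f"{name}.tsv", file_prov)
        (out_dir / "dendrogram.nwk").write_text(newick + "\n")
        (out_dir / "report.json").write_text(report.to_json(indent=2))
        (out_dir / "report.txt").write_text(report.summary_text() + "\n")
    return report
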