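"""End-to-end pipeline: DE -> compartments -> variability -> allele -> DMR -> repeats.

``run_full`` executes every stage on a study (simulated or read from disk),
writes tabular results plus a JSON run summary, and — when a truth table is
available — computes recovery metrics (compartment confusion, allele-class
accuracy, DMR and driver precision/recall).  All thresholds appear in the
summary for provenance, and a fixed seed upstream makes reruns bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import compartments as comp
from . import repeats as rep
from .allele import allelic_ratio, classify_allelic_change
from .de import (
    NormFactors,
    call_de,
    cpm,
    estimate_dispersion,
    filter_expressed,
    nb_contrast_test,
    tmm_factors,
)
from .io import CountMatrix, write_json_summary
from .methylation import annotate_dmr, call_dmrs, link_dmr_tss_deg
from .simulate import EXPECTED_COMPARTMENT, SimulatedStudy, TruthTable
from .variability import (
    diff_dispersion_test,
    group_cv,
    pca_scatter,
    sample_clustering,
    top_dispersed,
    vst_transform,
)

__all__ = ["PipelineParams", "PipelineResult", "run_full"]

logger = logging.getLogger("stagematch")

CONTRAST_DEFS = {
    "N6": ("WT6", "HOMO6"),
    "N12": ("WT12", "HOMO12"),
    "D_WT": ("WT12", "WT6"),
    "D_HOMO": ("HOMO12", "HOMO6"),
    "CONV": ("WT12", "HOMO6"),
    "MAT": ("MATMUT6", "MATWT6"),
}


@dataclass
class PipelineParams:
    """All tunable thresholds of the pipeline (defaults are the printed study cutoffs)."""

    cpm_min: float = 1.0
    min_samples: int = 2
    q_max: float = 0.05
    min_abs_log2fc: float = 1.2
    dispersion_q_max: float = 0.05
    dispersion_min_abs_log2fc: float = 1.5
    dmr_delta_min: float = 0.2
    dmr_max_gap: int = 300
    dmr_q_max: float = 0.05
    dmr_min_cpg: int = 12
    promoter_halfwidth: int = 1000
    cluster_max_gap: int = 50_000
    cluster_min_members: int = 3
    strand_s_min: float = 0.9
    flank_window: int = 10_000
    top_k_dispersed: int = 500
    de_method: str = "ql"


@dataclass
class PipelineResult:
    contrasts: dict
    memberships: pd.DataFrame
    threeway: pd.DataFrame
    assignment: object
    cv_by_compartment: pd.DataFrame
    pca: object
    clustering: object
    dispersion_result: object
    allele_classes: pd.DataFrame | None
    allele_proportions: pd.Series | None
    dmrs: object
    dmr_annotation: pd.DataFrame | None
    dmr_links: pd.DataFrame | None
    repeat_assignment: object
    family_tallies: pd.DataFrame | None
    driver_clusters: list
    cluster_rejections: list
    flanking: pd.DataFrame | None
    summary: dict


def _repeat_filter(counts: CountMatrix, lib: pd.Series, cpm_min: float, min_samples: int) -> CountMatrix:
    """Filter repeat loci by CPM relative to the overall (gene) library sizes."""
    eff = lib[counts.samples].to_numpy().astype(float)
    cpm_mat = counts.values / eff * 1e6
    keep = (cpm_mat > cpm_min).sum(axis=1) >= min_samples
    return CountMatrix(counts.data.loc[keep].copy(), kind=counts.kind)


def _combined_coverage(study: SimulatedStudy, samples: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    plus = [study.coverage[s][0] for s in samples if s in study.coverage]
    minus = [study.coverage[s][1] for s in samples if s in study.coverage]
    cols = ["chrom", "start", "end", "value"]
    plus_df = pd.concat(plus, ignore_index=True) if plus else pd.DataFrame(columns=cols)
    minus_df = pd.concat(minus, ignore_index=True) if minus else pd.DataFrame(columns=cols)
    return plus_df, minus_df


def run_full(
    study: SimulatedStudy,
    truth: TruthTable | None = None,
    params: PipelineParams | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage of the analysis on one study."""
    params = params or PipelineParams()
    sheet = study.sample_sheet
    groups = sheet.groups
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"thresholds": asdict(params), "stages": {}}

    # ----- DE core -----
    counts = filter_expressed(study.gene_counts, params.cpm_min, params.min_samples)
    logger.info("filter: %d of %d genes retained", len(counts.features), len(study.gene_counts.features))
    norm = tmm_factors(counts)
    disp = estimate_dispersion(counts, norm, groups)
    contrasts = {}
    available_groups = set(groups.to_numpy())
    for name, (a, b) in CONTRAST_DEFS.items():
        if a not in available_groups or b not in available_groups:
            logger.warning("contrast %s skipped: group missing", name)
            continue
        res = nb_contrast_test(
            counts, norm, disp, groups, (a, b),
            q_max=params.q_max, min_abs_log2fc=params.min_abs_log2fc,
            method=params.de_method,
        )
        contrasts[name] = res
        logger.info("%s: %d up, %d down", name, (res.calls == "up").sum(), (res.calls == "down").sum())
    summary["stages"]["filter"] = {"n_genes": int(len(counts.features))}
    summary["stages"]["contrasts"] = {
        n: {"up": int((r.calls == "up").sum()), "down": int((r.calls == "down").sum())}
        for n, r in contrasts.items()
    }

    # ----- compartments -----
    memberships = comp.membership_table({n: contrasts[n] for n in comp.CONTRAST_NAMES if n in contrasts})
    threeway = comp.three_way_decompose(memberships)
    assignment = comp.four_way_classify(memberships)
    log2cpm = cpm(counts, norm, log=True)
    tables = comp.compartment_tables(assignment, log2cpm, directory=out / "compartments" if out else None)
    summary["stages"]["compartments"] = {
        f"{label}|{direction}": int(len(tab)) for (label, direction), tab in tables.items()
    }
    summary["stages"]["threeway"] = {
        label: int(n) for label, n in threeway["label"].value_counts().items()
    }

    # ----- variability -----
    vst = vst_transform(counts, norm, dispersion=disp)
    cv_rows = []
    for (label, direction), tab in tables.items():
        if label in ("none",) or len(tab) < 1:
            continue
        mean_cv, _ = group_cv(vst, groups, tab.index)
        row = {"compartment": label, "direction": direction, "n_genes": len(tab)}
        row.update({f"cv_{g}": v for g, v in mean_cv.items()})
        cv_rows.append(row)
    cv_by_compartment = pd.DataFrame(cv_rows)

    deg_dwt = contrasts["D_WT"].de_features() if "D_WT" in contrasts else pd.Index([])
    pca = None
    if len(deg_dwt) >= 2:
        pca = pca_scatter(log2cpm, deg_dwt, groups)
    all_degs = pd.Index([])
    for res in contrasts.values():
        all_degs = all_degs.union(res.de_features())
    clustering = sample_clustering(log2cpm, all_degs) if len(all_degs) >= 1 else None

    dispersion_result = None
    top_disp: list[str] = []
    if "MATMUT6" in available_groups and "MATWT6" in available_groups:
        dispersion_result = diff_dispersion_test(
            counts, norm, groups, ("MATMUT6", "MATWT6"),
            q_max=params.dispersion_q_max, min_abs_log2fc=params.dispersion_min_abs_log2fc,
        )
        top_disp, _ = top_dispersed(dispersion_result, vst, k=params.top_k_dispersed)
        summary["stages"]["dispersion"] = {
            "n_called": int((dispersion_result.calls != "ns").sum())
        }

    # ----- allele classes -----
    allele_classes = allele_proportions = None
    if "MAT" in contrasts and dispersion_result is not None:
        profile = allelic_ratio(
            study.maternal_counts.subset(features=counts.features),
            study.paternal_counts.subset(features=counts.features),
            norm,
        )
        feature_set = contrasts["MAT"].de_features().union(dispersion_result.called_features())
        if len(feature_set):
            allele_classes, allele_proportions = classify_allelic_change(
                profile, feature_set, groups, "MATMUT6", "MATWT6"
            )
            summary["stages"]["allele"] = {
                k: float(v) for k, v in allele_proportions.items()
            }

    # ----- methylation -----
    dmrs = dmr_annotation = dmr_links = None
    if len(study.methylation) and study.wgbs_samples:
        wt_cols = [c for g, c in study.wgbs_samples.items() if g.startswith("WT")]
        homo_cols = [c for g, c in study.wgbs_samples.items() if not g.startswith("WT")]
        if wt_cols and homo_cols:
            dmrs = call_dmrs(
                study.methylation, wt_cols, homo_cols,
                delta_min=params.dmr_delta_min, max_gap=params.dmr_max_gap,
                q_max=params.dmr_q_max, min_cpg=params.dmr_min_cpg,
            )
            dmr_annotation = annotate_dmr(
                dmrs, study.gene_annotation, study.repeat_annotation,
                exons=study.exon_annotation, promoter_halfwidth=params.promoter_halfwidth,
            )
            dmr_links = link_dmr_tss_deg(dmr_annotation, assignment)
            summary["stages"]["dmr"] = {
                "n_dmrs": int(len(dmrs.table)),
                "n_promoter_dmrs": int((dmr_annotation["element"] == "promoter").sum()),
                "n_deg_links": int(len(dmr_links)),
            }
    else:
        logger.warning("methylation input missing: DMR stage skipped")

    # ----- repeats -----
    lib = pd.Series(
        study.gene_counts.values.sum(axis=0).astype(float), index=study.gene_counts.samples
    )
    rep_counts = _repeat_filter(study.repeat_counts, lib, params.cpm_min, params.min_samples)
    repeat_assignment = None
    family_tallies = None
    driver_clusters: list = []
    cluster_rejections: list = []
    flanking = None
    if len(rep_counts.features) >= 1 and len(contrasts) >= 4:
        rep_norm = NormFactors(
            lib_size=lib[rep_counts.samples],
            factors=norm.factors[rep_counts.samples],
        )
        rep_disp = estimate_dispersion(rep_counts, rep_norm, groups)
        rep_results = {}
        for name in comp.FOURWAY_CONTRASTS:
            a, b = CONTRAST_DEFS[name]
            if a not in available_groups or b not in available_groups:
                continue
            rep_results[name] = nb_contrast_test(
                rep_counts, rep_norm, rep_disp, groups, (a, b),
                q_max=params.q_max, min_abs_log2fc=params.min_abs_log2fc,
                method=params.de_method,
            )
        rep_memberships = comp.membership_table(rep_results)
        repeat_assignment = rep.classify_repeat_fourway(rep_memberships)

        subfam = rep.aggregate_subfamily(rep_counts, study.repeat_annotation)
        if "N6" in rep_results:
            subfam_norm = NormFactors(
                lib_size=lib[subfam.counts.samples], factors=norm.factors[subfam.counts.samples]
            )
            subfam_disp = estimate_dispersion(subfam.counts, subfam_norm, groups)
            subfam_res = nb_contrast_test(
                subfam.counts, subfam_norm, subfam_disp, groups, CONTRAST_DEFS["N6"],
                q_max=params.q_max, min_abs_log2fc=params.min_abs_log2fc,
                method=params.de_method,
            )
            family_tallies = rep.family_tally(subfam_res, subfam.lineage)

        # driver/passenger detection on loci DE between genotypes at 6 somites
        if "N6" in rep_results and study.coverage:
            calls = rep_results["N6"].calls
            de_loci = calls.index[calls != "ns"]
            ann = study.repeat_annotation.data.set_index("name")
            de_df = ann.loc[ann.index.intersection(de_loci), ["chrom", "start", "end"]].copy()
            de_df["direction"] = calls[de_df.index]
            clusters = rep.cluster_codirectional(
                de_df, max_gap=params.cluster_max_gap, min_members=params.cluster_min_members
            )
            homo_samples = [s for s in sheet.samples if groups[s] in ("HOMO6", "HOMO12")]
            cov_plus, cov_minus = _combined_coverage(study, homo_samples)
            dmr_table = dmrs.table if dmrs is not None else pd.DataFrame(
                columns=["chrom", "start", "end", "delta"]
            )
            for i, cl in enumerate(clusters):
                found = rep.find_driver(
                    cl, dmr_table, cov_plus, cov_minus, cluster_id=i, s_min=params.strand_s_min
                )
                if isinstance(found, rep.DriverCluster):
                    driver_clusters.append(found)
                else:
                    cluster_rejections.append(found)
            if driver_clusters:
                te_iv = ann.loc[[d.driver for d in driver_clusters], ["chrom", "start", "end"]]
                cov_by_group = {}
                for glabel, member_groups in (
                    ("WT", ("WT6", "WT12")),
                    ("HOMO", ("HOMO6", "HOMO12")),
                ):
                    gs = [s for s in sheet.samples if groups[s] in member_groups]
                    cov_by_group[glabel] = [study.coverage[s] for s in gs if s in study.coverage]
                flanking = rep.flanking_expression(
                    te_iv, cov_by_group, window=params.flank_window, chrom_sizes=study.chrom_sizes
                )
        summary["stages"]["repeats"] = {
            "n_loci": int(len(rep_counts.features)),
            "n_clusters_detected": int(len(driver_clusters) + len(cluster_rejections)),
            "n_driver_clusters": int(len(driver_clusters)),
        }

    # ----- recovery metrics against planted truth -----
    if truth is not None:
        summary["recovery"] = _recovery_metrics(
            truth, assignment, allele_classes, dmrs, driver_clusters
        )

    result = PipelineResult(
        contrasts=contrasts,
        memberships=memberships,
        threeway=threeway,
        assignment=assignment,
        cv_by_compartment=cv_by_compartment,
        pca=pca,
        clustering=clustering,
        dispersion_result=dispersion_result,
        allele_classes=allele_classes,
        allele_proportions=allele_proportions,
        dmrs=dmrs,
        dmr_annotation=dmr_annotation,
        dmr_links=dmr_links,
        repeat_assignment=repeat_assignment,
        family_tallies=family_tallies,
        driver_clusters=driver_clusters,
        cluster_rejections=cluster_rejections,
        flanking=flanking,
        summary=summary,
    )
    if out is not None:
        _write_outputs(result, out)
    return result


def match_dmrs(detected: pd.DataFrame, planted: pd.DataFrame) -> tuple[int, int]:
    """(number of detected DMRs overlapping a same-direction planted DMR,
    number of planted DMRs recovered by a same-direction detected DMR)."""
    def overlaps(a, b) -> bool:
        return a["chrom"] == b["chrom"] and a["start"] < b["end"] and b["start"] < a["end"] and (
            a["direction"] == b["direction"]
        )

    tp_detected = sum(
        any(overlaps(d, p) for _, p in planted.iterrows()) for _, d in detected.iterrows()
    )
    recovered = sum(
        any(overlaps(d, p) for _, d in detected.iterrows()) for _, p in planted.iterrows()
    )
    return int(tp_detected), int(recovered)


def _recovery_metrics(truth, assignment, allele_classes, dmrs, driver_clusters) -> dict:
    metrics: dict = {}
    expected = truth.expected_compartment()
    assigned = assignment.assignment.reindex(expected.index)
    both = expected.join(assigned, lsuffix="_true", rsuffix="_called").dropna()
    for cls in ("normal-both-stages", "develop-shared"):
        mask = both["label_true"] == cls
        if mask.any():
            correct = (
                (both.loc[mask, "label_called"] == cls)
                & (both.loc[mask, "direction_called"] == both.loc[mask, "direction_true"])
            )
            metrics[f"compartment_recovery_{cls}"] = float(correct.mean())
    switch = truth.genes.index[
        truth.genes["compartment_class"].isin(["ehmt2-switch-up", "ehmt2-switch-down"])
    ]
    if len(switch):
        called = assignment.assignment.reindex(switch)
        metrics["switch_in_develop_WT_only"] = float(
            (called["label"] == "develop-WT-only").mean()
        )
    confusion = (
        pd.crosstab(
            truth.genes["compartment_class"],
            assignment.assignment.reindex(truth.genes.index)["label"].fillna("filtered-out"),
        )
        .astype(int)
    )
    metrics["compartment_confusion"] = {
        str(t): {str(c): int(v) for c, v in row.items()} for t, row in confusion.iterrows()
    }

    if allele_classes is not None:
        expected_map = {
            "MAT-derepressed": "MAT-up",
            "both-derepressed-MAT-bias": "both-up-MAT-bias",
        }
        planted = truth.genes["allele_class"].map(expected_map).dropna()
        joined = allele_classes["allele_class"].reindex(planted.index).dropna()
        if len(joined):
            metrics["allele_accuracy_selected"] = float(
                (joined == planted[joined.index]).mean()
            )

    if dmrs is not None and len(truth.dmrs):
        tp, recovered = match_dmrs(dmrs.table, truth.dmrs)
        n_det = len(dmrs.table)
        metrics["dmr_precision"] = float(tp / n_det) if n_det else float("nan")
        metrics["dmr_recall"] = float(recovered / len(truth.dmrs))

    true_drivers = set(truth.repeats.index[truth.repeats["role"] == "driver"])
    if true_drivers:
        found = {d.driver for d in driver_clusters}
        tp = len(found & true_drivers)
        metrics["driver_precision"] = float(tp / len(found)) if found else float("nan")
        metrics["driver_recall"] = float(tp / len(true_drivers))
    return metrics


def _write_outputs(result: PipelineResult, out: Path) -> None:
    for name, res in result.contrasts.items():
        tab = res.table.copy()
        tab.index.name = "feature"
        tab.to_csv(out / f"contrast_{name}.tsv", sep="\t")
    result.memberships.rename_axis("feature").to_csv(out / "memberships.tsv", sep="\t")
    result.assignment.assignment.rename_axis("feature").to_csv(out / "compartments.tsv", sep="\t")
    result.threeway.to_csv(out / "threeway.tsv", sep="\t")
    if len(result.cv_by_compartment):
        result.cv_by_compartment.to_csv(out / "cv_by_compartment.tsv", sep="\t", index=False)
    if result.pca is not None:
        result.pca.coordinates.rename_axis("sample").to_csv(out / "pca_coords.tsv", sep="\t")
    if result.clustering is not None:
        result.clustering.distances.rename_axis("sample").to_csv(out / "distances.tsv", sep="\t")
    if result.dispersion_result is not None:
        tab = result.dispersion_result.table.copy()
        tab.index.name = "feature"
        tab.to_csv(out / "variability.tsv", sep="\t")
    if result.allele_classes is not None:
        result.allele_classes.rename_axis("feature").to_csv(out / "allele_classes.tsv", sep="\t")
        result.allele_proportions.rename_axis("class").to_csv(
            out / "allele_class_proportions.tsv", sep="\t"
        )
    if result.dmrs is not None:
        result.dmrs.table.to_csv(out / "dmrs.tsv", sep="\t", index=False)
    if result.dmr_annotation is not None:
        result.dmr_annotation.to_csv(out / "dmr_annotation.tsv", sep="\t", index=False)
    if result.dmr_links is not None:
        result.dmr_links.to_csv(out / "dmr_deg_links.tsv", sep="\t", index=False)
    if result.repeat_assignment is not None:
        result.repeat_assignment.assignment.rename_axis("locus").to_csv(
            out / "repeat_compartments.tsv", sep="\t"
        )
    if result.family_tallies is not None:
        result.family_tallies.to_csv(out / "family_tally.tsv", sep="\t")
    if result.driver_clusters:
        pd.DataFrame(
            [
                {
                    "cluster_id": d.cluster_id,
                    "chrom": d.chrom,
                    "start": d.start,
                    "end": d.end,
                    "direction": d.direction,
                    "strand": d.strand,
                    "strand_score": d.strand_score,
                    "driver": d.driver,
                    "n_passengers": len(d.passengers),
                    "span": d.span,
                }
                for d in result.driver_clusters
            ]
        ).to_csv(out / "driver_clusters.tsv", sep="\t", index=False)
    if result.flanking is not None:
        result.flanking.to_csv(out / "flanking_profiles.tsv", sep="\t", index=False)
    write_json_summary(result.summary, out / "run_summary.json")
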