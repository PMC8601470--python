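"""Simplified DMR detection from per-CpG beta values, and DMR-promoter-DEG linkage.

Candidate regions are maximal runs of CpGs with a consistent sign of the
(smoothed) between-group methylation difference, split at genomic gaps; each
candidate is tested with an exact Wilcoxon signed-rank test on the raw
per-CpG differences and candidates are BH-corrected.  A region is reported
as differentially methylated only when it contains at least ``min_cpg`` CpGs
(12 by default — a hard criterion), reaches BH q below ``q_max`` and a mean
difference of at least ``delta_min``.

With single-library bisulfite designs (one WT, one mutant methylome) the
"paired" differences are across CpGs within the region rather than across
replicates; the signed-rank null (independent equiprobable signs per CpG) is
then the declared working model.

The signed-rank distribution is computed exactly by dynamic programming over
(tie-averaged) ranks for regions up to 200 CpGs, so a uniform 12-CpG shift
yields exactly p = 2 * (1/2)**12; larger regions use the tie-corrected
normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .de import bh_adjust
from .io import FeatureAnnotation

__all__ = [
    "wilcoxon_signed_rank",
    "call_dmrs",
    "annotate_dmr",
    "link_dmr_tss_deg",
]

MIN_CPG_DEFAULT = 12
EXACT_WILCOXON_MAX_N = 200


def wilcoxon_signed_rank(diffs: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value, exact for n <= 200.

    Zero differences are dropped.  Ties are handled by average ranks; the
    exact null distribution of the positive-rank sum over all 2^n sign
    assignments is computed by dynamic programming on twice-the-ranks (which
    are integers even with .5 average ranks).  Above 200 informative CpGs the
    tie-corrected normal approximation is used.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d) & (d != 0.0)]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    scaled = np.round(2.0 * ranks).astype(np.int64)  # integers even with ties
    w_pos = int(scaled[d > 0].sum())
    total = int(scaled.sum())
    if n <= EXACT_WILCOXON_MAX_N:
        # dp[s] = number of sign assignments with positive-rank sum s
        dp = np.zeros(total + 1)
        dp[0] = 1.0
        for r in scaled:
            dp[r:] += dp[: total + 1 - r]
        dp /= 2.0**n
        p_le = float(dp[: w_pos + 1].sum())
        p_ge = float(dp[w_pos:].sum())
        return min(1.0, 2.0 * min(p_le, p_ge))
    # in scaled units: E[W+] = total/2, var[W+] = sum(scaled^2)/4
    mean = total / 2.0
    sd = 0.5 * np.sqrt(np.sum(scaled.astype(float) ** 2))
    z = (w_pos - mean) / sd
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


@dataclass
class DMRSet:
    """Called DMRs plus the candidate segments that were tested."""

    table: pd.DataFrame
    candidates: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


def _segment_signs(signs: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) index runs of constant nonzero sign."""
    runs = []
    i, n = 0, signs.size
    while i < n:
        if signs[i] == 0:
            i += 1
            continue
        j = i
        while j < n and signs[j] == signs[i]:
            j += 1
        runs.append((i, j))
        i = j
    return runs


def call_dmrs(
    meth: pd.DataFrame,
    samples_a,
    samples_b,
    delta_min: float = 0.2,
    max_gap: int = 300,
    q_max: float = 0.05,
    min_cpg: int = MIN_CPG_DEFAULT,
    smooth_window: int = 5,
) -> DMRSet:
    """Segment the CpG table and report differentially methylated regions.

    ``delta`` at each CpG is mean(beta over A samples) - mean(beta over B),
    with missing calls excluded per CpG; positive delta means hypermethylated
    in A.  Runs of CpGs are split at gaps > ``max_gap`` bp, smoothed with a
    centered running mean (window ``smooth_window``), and sub-segmented at
    sign changes of the smoothed delta.  Only segments with at least
    ``min_cpg`` CpGs are tested, so no reported DMR can ever fall below the
    CpG floor.
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    for col in samples_a + samples_b:
        if col not in meth.columns:
            raise ValueError(f"sample column {col!r} missing from methylation table")
    cand_rows = []
    for chrom, sub in meth.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"CpG positions not strictly increasing on {chrom}")
        beta_a = sub[samples_a].mean(axis=1, skipna=True).to_numpy()
        beta_b = sub[samples_b].mean(axis=1, skipna=True).to_numpy()
        delta = beta_a - beta_b
        ok = np.isfinite(delta)
        pos, delta = pos[ok], delta[ok]
        beta_a, beta_b = beta_a[ok], beta_b[ok]
        if pos.size == 0:
            continue
        # split at large genomic gaps
        breaks = np.where(np.diff(pos) > max_gap)[0] + 1
        for block in np.split(np.arange(pos.size), breaks):
            if block.size < min_cpg:
                continue
            d_block = delta[block]
            smoothed = (
                pd.Series(d_block).rolling(smooth_window, center=True, min_periods=1).mean()
            ).to_numpy()
            for i0, i1 in _segment_signs(np.sign(smoothed)):
                if i1 - i0 < min_cpg:
                    continue
                idx = block[i0:i1]
                raw = delta[idx]
                cand_rows.append(
                    {
                        "chrom": chrom,
                        "start": int(pos[idx[0]]),
                        "end": int(pos[idx[-1]]) + 1,
                        "n_cpg": int(idx.size),
                        "mean_a": float(beta_a[idx].mean()),
                        "mean_b": float(beta_b[idx].mean()),
                        "delta": float(raw.mean()),
                        "pvalue": wilcoxon_signed_rank(raw),
                    }
                )
    candidates = pd.DataFrame(
        cand_rows,
        columns=["chrom", "start", "end", "n_cpg", "mean_a", "mean_b", "delta", "pvalue"],
    )
    if candidates.empty:
        table = candidates.assign(qvalue=pd.Series(dtype=float), direction=pd.Series(dtype=str))
        return DMRSet(table=table, candidates=candidates)
    candidates["qvalue"] = bh_adjust(candidates["pvalue"]).to_numpy()
    keep = (candidates["qvalue"] < q_max) & (candidates["delta"].abs() >= delta_min)
    table = candidates.loc[keep].copy()
    table["direction"] = np.where(table["delta"] > 0, "hyper", "hypo")
    table = table.sort_values(["chrom", "start"]).reset_index(drop=True)
    return DMRSet(table=table, candidates=candidates)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def _trees(annotation: FeatureAnnotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in annotation.data.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.name)
    return trees


def annotate_dmr(
    dmrs: DMRSet | pd.DataFrame,
    genes: FeatureAnnotation,
    repeats: FeatureAnnotation | None = None,
    exons: FeatureAnnotation | None = None,
    promoter_halfwidth: int = 1000,
) -> pd.DataFrame:
    """Assign each DMR a genomic element class and its nearest gene.

    Priority: promoter (TSS +/- ``promoter_halfwidth``) > exon > intron >
    intergenic; overlap with an annotated repeat is recorded independently of
    the element class.  If no exon annotation is supplied, gene bodies count
    as exonic.  Distance to the nearest TSS is signed by gene strand
    (positive = DMR center downstream of the TSS), zero when the DMR spans
    the TSS.
    """
    table = dmrs.table if isinstance(dmrs, DMRSet) else dmrs
    gene_df = genes.data
    tss = genes.tss()
    promoters: dict[str, IntervalTree] = {}
    bodies: dict[str, IntervalTree] = {}
    for row, t in zip(gene_df.itertuples(index=False), tss.to_numpy()):
        promoters.setdefault(row.chrom, IntervalTree()).addi(
            max(0, int(t) - promoter_halfwidth), int(t) + promoter_halfwidth + 1, row.name
        )
        bodies.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.name)
    exon_trees = _trees(exons) if exons is not None else None
    repeat_trees = _trees(repeats) if repeats is not None else {}
    repeat_sub = (
        repeats.data.set_index("name")["subfamily"] if repeats is not None else pd.Series(dtype=str)
    )

    tss_by_chrom: dict[str, pd.DataFrame] = {
        chrom: pd.DataFrame(
            {
                "tss": tss.to_numpy()[gene_df["chrom"].to_numpy() == chrom],
                "name": gene_df.loc[gene_df["chrom"] == chrom, "name"].to_numpy(),
                "strand": gene_df.loc[gene_df["chrom"] == chrom, "strand"].to_numpy(),
            }
        )
        for chrom in gene_df["chrom"].unique()
    }

    rows = []
    for i, dmr in table.iterrows():
        chrom, start, end = dmr["chrom"], int(dmr["start"]), int(dmr["end"])
        center = (start + end) // 2
        prom_hits = promoters.get(chrom, IntervalTree()).overlap(start, end)
        if prom_hits:
            element = "promoter"
        elif exon_trees is None:
            element = "exon" if bodies.get(chrom, IntervalTree()).overlap(start, end) else "intergenic"
        elif exon_trees.get(chrom, IntervalTree()).overlap(start, end):
            element = "exon"
        elif bodies.get(chrom, IntervalTree()).overlap(start, end):
            element = "intron"
        else:
            element = "intergenic"
        te_hits = repeat_trees.get(chrom, IntervalTree()).overlap(start, end)
        te_name = sorted(h.data for h in te_hits)[0] if te_hits else ""
        nearest, distance = "", np.nan
        cand = tss_by_chrom.get(chrom)
        if cand is not None and len(cand):
            d = center - cand["tss"].to_numpy()
            j = int(np.argmin(np.abs(d)))
            nearest = cand["name"].iloc[j]
            t = int(cand["tss"].iloc[j])
            if start <= t < end:
                distance = 0
            else:
                signed = center - t
                distance = -signed if cand["strand"].iloc[j] == "-" else signed
        rows.append(
            {
                "dmr_index": i,
                "chrom": chrom,
                "start": start,
                "end": end,
                "element": element,
                "nearest_gene": nearest,
                "tss_distance": distance,
                "te_overlap": te_name,
                "te_subfamily": repeat_sub.get(te_name, "") if te_name else "",
                "direction": dmr.get("direction", ""),
                "delta": dmr.get("delta", np.nan),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "dmr_index",
            "chrom",
            "start",
            "end",
            "element",
            "nearest_gene",
            "tss_distance",
            "te_overlap",
            "te_subfamily",
            "direction",
            "delta",
        ],
    )


def link_dmr_tss_deg(
    dmr_annotation: pd.DataFrame,
    assignment,
) -> pd.DataFrame:
    """Concordance of promoter DMRs with the expression behaviour of their gene.

    For each differentially expressed gene carrying a promoter DMR (WT vs
    mutant methylation difference, ``hyper`` = hypermethylated in WT):

    * promoter hyper in WT and gene expressed lower in WT: the factor both
      methylates the promoter and keeps the gene silent
      (``methylates-and-silences``);
    * promoter hypo in WT and gene expressed higher in WT: the factor keeps
      the promoter hypomethylated and the gene active
      (``keeps-hypomethylated-and-expressed``);
    * anything else: ``discordant``.

    Genes without a promoter DMR, or without a DE compartment, are absent
    from the result.  ``assignment`` is a CompartmentAssignment (or its
    ``assignment`` frame with ``label``/``direction`` columns).
    """
    assign_df = getattr(assignment, "assignment", assignment)
    promoter_dmrs = dmr_annotation[dmr_annotation["element"] == "promoter"]
    rows = []
    for dmr in promoter_dmrs.itertuples(index=False):
        gene = dmr.nearest_gene
        if gene not in assign_df.index:
            continue
        label = assign_df.loc[gene, "label"]
        direction = assign_df.loc[gene, "direction"]
        if label in ("none",) or direction == "ns":
            continue
        if dmr.direction == "hyper" and direction == "down":
            concordance = "methylates-and-silences"
        elif dmr.direction == "hypo" and direction == "up":
            concordance = "keeps-hypomethylated-and-expressed"
        else:
            concordance = "discordant"
        rows.append(
            {
                "gene": gene,
                "dmr_index": dmr.dmr_index,
                "dmr_direction": dmr.direction,
                "gene_direction": direction,
                "compartment": label,
                "concordance": concordance,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "dmr_index",
            "dmr_direction",
            "gene_direction",
            "compartment",
            "concordance",
        ],
    )
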