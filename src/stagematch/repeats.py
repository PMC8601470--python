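"""Repeat-locus analyses: subfamily tallies, four-way classification, and
driver/passenger read-through cluster detection.

Hypomethylated LTR retrotransposons (prominently ERVK family members) can
fire long unidirectional transcripts in the mutant that run through many
downstream repeat loci.  Those loci then score as differentially expressed
("passengers") although the transcription initiates at a single
DMR-overlapping "driver" element at the transcript's 5' end.  The detector
first merges consecutive co-directional DE repeat loci into clusters by a
linear genomic scan, then — per cluster — determines the transcript strand
from stranded coverage, requires near-complete strand consistency of the
signal, and anchors the cluster to the DMR-overlapping member nearest the
transcript's 5' end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .compartments import CompartmentAssignment, four_way_classify
from .de import ContrastResults
from .io import CountMatrix, FeatureAnnotation

__all__ = [
    "SubfamilyCounts",
    "DriverCluster",
    "ClusterRejection",
    "aggregate_subfamily",
    "family_tally",
    "classify_repeat_fourway",
    "cluster_codirectional",
    "strand_consistency",
    "find_driver",
    "flanking_expression",
]


# ---------------------------------------------------------------------------
# subfamily aggregation and family tallies
# ---------------------------------------------------------------------------


@dataclass
class SubfamilyCounts:
    """Subfamily x sample counts (exact integer sums over member loci)."""

    counts: CountMatrix
    lineage: pd.DataFrame  # subfamily -> family


def aggregate_subfamily(
    locus_counts: CountMatrix, annotation: FeatureAnnotation
) -> SubfamilyCounts:
    """Sum locus-level counts into subfamily-level counts, keeping lineage.

    Loci missing from the annotation (or with an empty subfamily) are summed
    into an ``unassigned`` bucket with a warning.
    """
    ann = annotation.data.set_index("name")
    sub = ann["subfamily"].reindex(locus_counts.features).fillna("")
    unknown = sub[sub == ""].index
    if len(unknown):
        warnings.warn(
            f"{len(unknown)} locus/loci without subfamily assigned to 'unassigned'",
            stacklevel=2,
        )
        sub[unknown] = "unassigned"
    grouped = locus_counts.data.groupby(sub.to_numpy()).sum()
    grouped.index.name = "subfamily"
    fam = (
        ann.loc[ann.index.isin(locus_counts.features), ["subfamily", "family"]]
        .drop_duplicates("subfamily")
        .set_index("subfamily")["family"]
    )
    lineage = pd.DataFrame(
        {"family": fam.reindex(grouped.index).fillna("unassigned")}
    )
    return SubfamilyCounts(
        counts=CountMatrix(grouped, kind="repeat_subfamily"), lineage=lineage
    )


def family_tally(
    subfamily_result: ContrastResults, lineage: pd.DataFrame
) -> pd.DataFrame:
    """Per repeat family: number of subfamilies called up / down in a contrast.

    Families whose subfamilies are all non-significant are absent from the
    tally.
    """
    calls = subfamily_result.table["call"]
    fam = lineage["family"].reindex(calls.index).fillna("unassigned")
    de = calls[calls != "ns"]
    if de.empty:
        return pd.DataFrame(columns=["family", "n_up", "n_down"]).set_index("family")
    tab = (
        pd.DataFrame({"family": fam[de.index], "call": de})
        .groupby(["family", "call"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    out = pd.DataFrame(
        {
            "n_up": tab.get("up", pd.Series(0, index=tab.index)),
            "n_down": tab.get("down", pd.Series(0, index=tab.index)),
        }
    )
    out.index.name = "family"
    return out


def classify_repeat_fourway(memberships: pd.DataFrame) -> CompartmentAssignment:
    """Four-way compartment classification of repeat loci (same rules as genes)."""
    return four_way_classify(memberships)


# ---------------------------------------------------------------------------
# co-directional clustering
# ---------------------------------------------------------------------------


def cluster_codirectional(
    de_loci: pd.DataFrame,
    max_gap: int = 50_000,
    min_members: int = 3,
) -> list[pd.DataFrame]:
    """Merge consecutive same-direction DE loci into clusters by a linear scan.

    ``de_loci`` needs columns chrom, start, end, direction (up/down) and is
    indexed by locus id.  Two consecutive loci join the same cluster when
    they lie on one chromosome, share the direction, and the gap between
    them (start of the next minus end of the previous) is at most
    ``max_gap``.  Clusters with fewer than ``min_members`` loci are dropped.
    Every locus belongs to at most one cluster.
    """
    required = {"chrom", "start", "end", "direction"}
    missing = required - set(de_loci.columns)
    if missing:
        raise ValueError(f"de_loci lacks columns: {sorted(missing)}")
    loci = de_loci.sort_values(["chrom", "start", "end"], kind="mergesort")
    clusters: list[pd.DataFrame] = []
    current: list = []

    def flush() -> None:
        if len(current) >= min_members:
            clusters.append(loci.loc[[i for i, _ in current]])

    prev = None
    for idx, row in loci.iterrows():
        if (
            prev is not None
            and row["chrom"] == prev["chrom"]
            and row["direction"] == prev["direction"]
            and row["start"] - prev["end"] <= max_gap
        ):
            current.append((idx, row))
        else:
            flush()
            current = [(idx, row)]
        prev = row
    flush()
    return clusters


# ---------------------------------------------------------------------------
# stranded coverage
# ---------------------------------------------------------------------------


def _interval_signal(track: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    """Integrated coverage (value x overlapped bp) of a bedGraph over an interval."""
    sub = track[track["chrom"] == chrom]
    if sub.empty or end <= start:
        return 0.0
    s = np.maximum(sub["start"].to_numpy(), start)
    e = np.minimum(sub["end"].to_numpy(), end)
    overlap = np.clip(e - s, 0, None)
    return float(np.sum(overlap * sub["value"].to_numpy()))


def strand_consistency(
    cov_plus: pd.DataFrame, cov_minus: pd.DataFrame, chrom: str, start: int, end: int
) -> float:
    """Fraction of read signal on the majority strand within an interval.

    ``S = max(cov+, cov-) / (cov+ + cov-)``; NA when the interval has no
    signal on either strand.  Near 1 for a single read-through transcript.
    """
    plus = _interval_signal(cov_plus, chrom, start, end)
    minus = _interval_signal(cov_minus, chrom, start, end)
    total = plus + minus
    if total <= 0:
        return float("nan")
    return max(plus, minus) / total


# ---------------------------------------------------------------------------
# driver detection
# ---------------------------------------------------------------------------


@dataclass
class DriverCluster:
    cluster_id: int
    chrom: str
    start: int
    end: int
    direction: str
    strand: str
    strand_score: float
    driver: str
    dmr_index: int
    passengers: list[str] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class ClusterRejection:
    cluster_id: int
    chrom: str
    start: int
    end: int
    reason: str  # no-dmr-te | low-strand-consistency | no-signal


def find_driver(
    cluster: pd.DataFrame,
    dmrs: pd.DataFrame,
    cov_plus: pd.DataFrame,
    cov_minus: pd.DataFrame,
    cluster_id: int = 0,
    s_min: float = 0.9,
) -> DriverCluster | ClusterRejection:
    """Anchor a co-directional cluster to its DMR-bearing driver element.

    The transcript strand is the majority strand of coverage within the
    cluster interval; the driver is the DMR-overlapping member nearest the
    transcript's 5' end (leftmost cluster boundary for +, rightmost for -).
    Ties between candidate drivers are broken by the larger |methylation
    delta| of their DMR.  Clusters without a DMR-overlapping member or with
    strand consistency below ``s_min`` are rejected with a reason.
    """
    chrom = cluster["chrom"].iloc[0]
    start = int(cluster["start"].min())
    end = int(cluster["end"].max())
    plus = _interval_signal(cov_plus, chrom, start, end)
    minus = _interval_signal(cov_minus, chrom, start, end)
    total = plus + minus
    if total <= 0:
        return ClusterRejection(cluster_id, chrom, start, end, "no-signal")
    score = max(plus, minus) / total
    if score < s_min:
        return ClusterRejection(cluster_id, chrom, start, end, "low-strand-consistency")
    strand = "+" if plus >= minus else "-"

    dmr_sub = dmrs[dmrs["chrom"] == chrom]
    tree = IntervalTree()
    for i, d in dmr_sub.iterrows():
        tree.addi(int(d["start"]), int(d["end"]), i)
    five_prime = start if strand == "+" else end
    candidates = []
    for locus_id, row in cluster.iterrows():
        hits = tree.overlap(int(row["start"]), int(row["end"]))
        if not hits:
            continue
        anchor = int(row["start"]) if strand == "+" else int(row["end"])
        for h in hits:
            delta = abs(float(dmrs.loc[h.data].get("delta", 0.0)))
            candidates.append((abs(anchor - five_prime), -delta, str(locus_id), h.data))
    if not candidates:
        return ClusterRejection(cluster_id, chrom, start, end, "no-dmr-te")
    candidates.sort()
    _, _, driver, dmr_index = candidates[0]
    passengers = [str(i) for i in cluster.index if str(i) != driver]
    return DriverCluster(
        cluster_id=cluster_id,
        chrom=chrom,
        start=start,
        end=end,
        direction=cluster["direction"].iloc[0],
        strand=strand,
        strand_score=float(score),
        driver=driver,
        dmr_index=dmr_index,
        passengers=passengers,
    )


# ---------------------------------------------------------------------------
# flanking expression
# ---------------------------------------------------------------------------


def flanking_expression(
    te_intervals: pd.DataFrame,
    coverage_by_group: dict[str, list[tuple[pd.DataFrame, pd.DataFrame]]],
    window: int = 10_000,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean log2 coverage (CPM-scaled, + 1) in 10-kb windows flanking each TE.

    ``te_intervals`` has columns chrom, start, end and is indexed by TE id;
    ``coverage_by_group`` maps a group label to a list of per-sample
    (plus, minus) bedGraph pairs; strands are summed, each sample is scaled
    to its total signal (CPM-like) and samples of a group are averaged.
    Windows are clipped at chromosome bounds.
    """
    rows = []
    for te_id, te in te_intervals.iterrows():
        chrom, start, end = te["chrom"], int(te["start"]), int(te["end"])
        size = chrom_sizes.get(chrom) if chrom_sizes else None
        up_lo = max(0, start - window)
        up_hi = start
        dn_lo = end
        dn_hi = min(size, end + window) if size else end + window
        for group, tracks in coverage_by_group.items():
            up_vals, dn_vals = [], []
            for cov_plus, cov_minus in tracks:
                total = float(cov_plus["value"].mul(cov_plus["end"] - cov_plus["start"]).sum())
                total += float(cov_minus["value"].mul(cov_minus["end"] - cov_minus["start"]).sum())
                scale = 1e6 / total if total > 0 else 0.0
                up = sum(
                    _interval_signal(t, chrom, up_lo, up_hi) for t in (cov_plus, cov_minus)
                )
                dn = sum(
                    _interval_signal(t, chrom, dn_lo, dn_hi) for t in (cov_plus, cov_minus)
                )
                up_width = max(up_hi - up_lo, 1)
                dn_width = max(dn_hi - dn_lo, 1)
                up_vals.append(np.log2(up / up_width * scale + 1.0))
                dn_vals.append(np.log2(dn / dn_width * scale + 1.0))
            rows.append(
                {
                    "te": te_id,
                    "group": group,
                    "upstream": float(np.mean(up_vals)) if up_vals else 0.0,
                    "downstream": float(np.mean(dn_vals)) if dn_vals else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["te", "group", "upstream", "downstream"])
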