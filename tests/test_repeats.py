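import numpy as np
import pandas as pd
import pytest

from stagematch import (
    aggregate_subfamily,
    cluster_codirectional,
    family_tally,
    find_driver,
    flanking_expression,
    strand_consistency,
)
from stagematch.de import ContrastResults
from stagematch.io import FeatureAnnotation
from stagematch.repeats import ClusterRejection, DriverCluster
from conftest import count_matrix
from oracles import clusters_reference


def _annotation(rows):
    return FeatureAnnotation(
        pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "name", "score", "strand", "subfamily", "family"],
        )
    )


def _track(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


# ---------------------------------------------------------------------------
# aggregation and tallies
# ---------------------------------------------------------------------------


def test_subfamily_aggregation_sums_and_conserves():
    ann = _annotation(
        [
            ("chr1", 0, 100, "r0", 0, "+", "RLTR17", "ERVK"),
            ("chr1", 200, 300, "r1", 0, "+", "RLTR17", "ERVK"),
            ("chr1", 400, 500, "r2", 0, "-", "L1MdA", "L1"),
        ]
    )
    cm = count_matrix([[3, 1], [4, 2], [5, 0]], prefix="r")
    agg = aggregate_subfamily(cm, ann)
    assert agg.counts.data.loc["RLTR17"].tolist() == [7, 3]
    assert agg.counts.data.sum().tolist() == cm.data.sum().tolist()
    assert agg.lineage.loc["RLTR17", "family"] == "ERVK"
    empty = aggregate_subfamily(count_matrix(np.empty((0, 2), dtype=int), prefix="r"), ann)
    assert len(empty.counts.data) == 0


def test_unknown_subfamily_goes_to_unassigned_with_warning():
    ann = _annotation([("chr1", 0, 100, "r0", 0, "+", "RLTR17", "ERVK")])
    cm = count_matrix([[3], [4]], prefix="r")  # r1 not annotated
    with pytest.warns(UserWarning, match="unassigned"):
        agg = aggregate_subfamily(cm, ann)
    assert agg.counts.data.loc["unassigned"].tolist() == [4]


def test_family_tally_counts_and_drops_ns():
    table = pd.DataFrame(
        {
            "log2fc": [2, -2, 2, 0],
            "pvalue": 0.001,
            "qvalue": 0.001,
            "mean_cpm_a": 1.0,
            "mean_cpm_b": 1.0,
            "call": ["up", "down", "up", "ns"],
        },
        index=["sub_a", "sub_b", "sub_c", "sub_d"],
    )
    lineage = pd.DataFrame(
        {"family": ["ERVK", "ERVK", "ERVK", "L1"]}, index=["sub_a", "sub_b", "sub_c", "sub_d"]
    )
    tally = family_tally(ContrastResults(("A", "B"), table), lineage)
    assert tally.loc["ERVK", "n_up"] == 2
    assert tally.loc["ERVK", "n_down"] == 1
    assert "L1" not in tally.index  # all-ns family absent
    assert tally[["n_up", "n_down"]].to_numpy().sum() == 3  # conservation


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _loci_frame(items):
    return pd.DataFrame(items).set_index("name")


def test_cluster_simple_run_of_five():
    items = [
        {"name": f"r{i}", "chrom": "chr1", "start": 10_000 * (i + 1), "end": 10_000 * (i + 1) + 500,
         "direction": "up"}
        for i in range(5)
    ]
    clusters = cluster_codirectional(_loci_frame(items), max_gap=50_000, min_members=3)
    assert len(clusters) == 1
    assert len(clusters[0]) == 5


def test_cluster_direction_change_splits_runs():
    directions = ["up", "up", "down", "up", "up"]
    items = [
        {"name": f"r{i}", "chrom": "chr1", "start": 10_000 * (i + 1),
         "end": 10_000 * (i + 1) + 500, "direction": d}
        for i, d in enumerate(directions)
    ]
    assert cluster_codirectional(_loci_frame(items), max_gap=50_000, min_members=3) == []


def test_cluster_never_merges_across_chromosomes():
    items = [
        {"name": f"r{i}", "chrom": c, "start": 1000, "end": 1500, "direction": "up"}
        for i, c in enumerate(["chr1", "chr2", "chr3"])
    ]
    assert cluster_codirectional(_loci_frame(items), max_gap=10**9, min_members=3) == []


@pytest.mark.parametrize("seed", range(100))
def test_cluster_matches_bruteforce_enumeration(seed):
    """Linear scan equals the O(n^2) run-enumeration oracle on random instances."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 40))
    items = []
    for i in range(n):
        start = int(rng.integers(0, 500_000))
        items.append(
            {
                "name": f"r{i}",
                "chrom": f"chr{rng.integers(1, 3)}",
                "start": start,
                "end": start + int(rng.integers(100, 2_000)),
                "direction": "up" if rng.random() < 0.5 else "down",
            }
        )
    max_gap = int(rng.integers(1_000, 60_000))
    min_members = int(rng.integers(2, 5))
    ours = cluster_codirectional(_loci_frame(items), max_gap=max_gap, min_members=min_members)
    ours_sets = [list(c.index) for c in ours]
    assert ours_sets == clusters_reference(items, max_gap, min_members)


# ---------------------------------------------------------------------------
# strand consistency and drivers
# ---------------------------------------------------------------------------


def test_strand_consistency_arithmetic():
    plus = _track([("chr1", 0, 100, 1.0)])
    minus = _track([("chr1", 0, 100, 0.0)])
    assert strand_consistency(plus, minus, "chr1", 0, 100) == pytest.approx(1.0)
    minus9 = _track([("chr1", 0, 10, 1.0)])
    plus90 = _track([("chr1", 0, 90, 1.0)])
    assert strand_consistency(plus90, minus9, "chr1", 0, 100) == pytest.approx(0.9)
    empty = _track([])
    assert np.isnan(strand_consistency(empty, empty, "chr1", 0, 100))


def _cluster_frame():
    rows = []
    for i in range(7):
        start = 100_000 + i * 5_000
        rows.append({"name": f"r{i}", "chrom": "chr1", "start": start, "end": start + 500,
                     "direction": "down"})
    return _loci_frame(rows)


def test_find_driver_recovers_planted_driver():
    cluster = _cluster_frame()
    dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [100_100], "end": [100_400], "delta": [0.4]})
    plus = _track([("chr1", 100_000, 140_000, 5.0)])
    minus = _track([])
    out = find_driver(cluster, dmrs, plus, minus, cluster_id=3)
    assert isinstance(out, DriverCluster)
    assert out.driver == "r0"  # DMR-bearing member at the 5' end
    assert out.strand == "+"
    assert out.strand_score == pytest.approx(1.0)
    assert sorted(out.passengers) == [f"r{i}" for i in range(1, 7)]
    assert out.cluster_id == 3


def test_find_driver_rejects_balanced_strands():
    cluster = _cluster_frame()
    dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [100_100], "end": [100_400], "delta": [0.4]})
    both = _track([("chr1", 100_000, 140_000, 5.0)])
    out = find_driver(cluster, dmrs, both, both.copy())
    assert isinstance(out, ClusterRejection)
    assert out.reason == "low-strand-consistency"


def test_find_driver_rejects_without_dmr_te():
    cluster = _cluster_frame()
    dmrs = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [100], "delta": [0.4]})
    plus = _track([("chr1", 100_000, 140_000, 5.0)])
    out = find_driver(cluster, dmrs, plus, _track([]))
    assert isinstance(out, ClusterRejection)
    assert out.reason == "no-dmr-te"


def test_find_driver_five_prime_rule_on_minus_strand():
    cluster = _cluster_frame()
    # two DMR-bearing members; coverage on minus strand -> 5' end is the right edge
    dmrs = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [100_100, 130_100], "end": [100_400, 130_400],
         "delta": [0.4, 0.4]}
    )
    minus = _track([("chr1", 95_000, 135_000, 5.0)])
    out = find_driver(cluster, dmrs, _track([]), minus)
    assert out.strand == "-"
    assert out.driver == "r6"  # nearest the 3'-most genomic coordinate


# ---------------------------------------------------------------------------
# flanking expression
# ---------------------------------------------------------------------------


def test_flanking_zero_coverage_and_clipping():
    te = pd.DataFrame({"chrom": ["chr1"], "start": [4_000], "end": [5_000]}, index=["te0"])
    empty = _track([])
    prof = flanking_expression(te, {"WT": [(empty, empty)]}, window=10_000,
                               chrom_sizes={"chr1": 8_000})
    row = prof.iloc[0]
    assert row["upstream"] == pytest.approx(0.0)
    assert row["downstream"] == pytest.approx(0.0)


def test_flanking_detects_downstream_readthrough():
    te = pd.DataFrame({"chrom": ["chr1"], "start": [50_000], "end": [51_000]}, index=["driver"])
    homo_plus = _track([("chr1", 50_000, 80_000, 5.0)])
    empty = _track([])
    prof = flanking_expression(
        te,
        {"HOMO": [(homo_plus, empty)], "WT": [(empty, empty)]},
        window=10_000,
    )
    prof = prof.set_index("group")
    assert prof.loc["HOMO", "downstream"] > prof.loc["HOMO", "upstream"]
    assert prof.loc["WT", "downstream"] == pytest.approx(prof.loc["WT", "upstream"])
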