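import numpy as np
import pandas as pd
import pytest

from stagematch import (
    SimConfig,
    estimate_dispersion,
    filter_expressed,
    nb_contrast_test,
    read_study,
    simulate_study,
    tmm_factors,
    write_study,
)
from conftest import SMALL_CONFIG


def test_fixed_seed_is_bit_identical():
    a_study, a_truth = simulate_study(SimConfig(seed=5, **SMALL_CONFIG))
    b_study, b_truth = simulate_study(SimConfig(seed=5, **SMALL_CONFIG))
    assert a_study.gene_counts.data.equals(b_study.gene_counts.data)
    assert a_study.repeat_counts.data.equals(b_study.repeat_counts.data)
    assert a_study.methylation.equals(b_study.methylation)
    assert a_truth.genes.equals(b_truth.genes)
    for s in a_study.coverage:
        assert a_study.coverage[s][0].equals(b_study.coverage[s][0])


def test_invalid_configs_raise():
    with pytest.raises(ValueError, match="sum to <= 1"):
        SimConfig(fractions={"null": 0.9, "normal-both-up": 0.2}).validate()
    with pytest.raises(ValueError, match="unknown gene classes"):
        SimConfig(fractions={"wiggle": 0.1}).validate()
    with pytest.raises(ValueError, match="replicates"):
        SimConfig(replicates_per_group=1).validate()
    with pytest.raises(ValueError, match="12 CpGs"):
        SimConfig(dmr_n_cpg=8).validate()


def test_truth_table_partitions_features(small_study):
    study, truth = small_study
    assert truth.genes.index.equals(study.gene_counts.features)
    assert not truth.genes.index.duplicated().any()
    assert set(truth.repeats.index) == set(study.repeat_counts.features)
    # passengers lie within their driver's cluster interval
    ann = study.repeat_annotation.data.set_index("name")
    for cid, members in truth.repeats.groupby("cluster_id"):
        if cid < 0:
            continue
        iv = ann.loc[members.index]
        driver = members.index[members["role"] == "driver"]
        assert len(driver) == 1
        lo, hi = iv["start"].min(), iv["end"].max()
        passengers = ann.loc[members.index[members["role"] == "passenger"]]
        assert (passengers["start"] >= lo).all() and (passengers["end"] <= hi).all()


def test_allele_counts_never_exceed_totals(small_study):
    study, _ = small_study
    total = study.gene_counts.values
    mat = study.maternal_counts.values
    pat = study.paternal_counts.values
    assert (mat >= 0).all() and (pat >= 0).all()
    assert ((mat + pat) <= total).all()


def test_cluster_coverage_is_single_stranded(small_study):
    """Planted read-through clusters put coverage on exactly one strand."""
    study, truth = small_study
    ann = study.repeat_annotation.data.set_index("name")
    groups = study.groups
    for cid, members in truth.repeats.groupby("cluster_id"):
        if cid < 0:
            continue
        iv = ann.loc[members.index]
        lo, hi = int(iv["start"].min()), int(iv["end"].max())
        strand = members["strand"].iloc[0]
        for sample, (plus, minus) in study.coverage.items():
            if groups[sample] not in ("HOMO6", "HOMO12"):
                continue
            wrong = minus if strand == "+" else plus
            sub = wrong[(wrong["chrom"] == "chr1") & (wrong["start"] < hi) & (wrong["end"] > lo)]
            assert len(sub) == 0


def test_planted_moments_match_nb_closed_form():
    """Pooled empirical moments of switch genes match var = mu + phi mu^2.

    Baseline, dispersion and library-size priors are made degenerate so all
    switch genes share (mu=300, phi=0.1), with phi inflated fourfold in the
    6-somite mutant; pooling genes x replicates x seeds gives >10,000 draws
    per condition.
    """
    mu, phi, inflation = 300.0, 0.1, 4.0
    homo6_vals, wt6_vals = [], []
    for seed in range(80):
        cfg = SimConfig(
            n_genes=40,
            n_repeat_loci=30,
            n_drivers=2,
            passengers_per_driver=3,
            n_independent_de_repeats=4,
            n_tss_dmrs=2,
            replicates_per_group=4,
            lib_size_log_sd=0.0,
            planted_mu_log_mean=float(np.log(mu)),
            planted_mu_log_sd=0.0,
            planted_mu_min=mu,
            dispersion_shape=1e7,
            dispersion_rate=1e7 / phi,
            inflation_factor=inflation,
            fractions={"ehmt2-switch-up": 0.5},
            seed=seed,
        )
        study, truth = simulate_study(cfg)
        switch = truth.genes["compartment_class"] == "ehmt2-switch-up"
        homo6 = [s for s in study.sample_sheet.samples if study.groups[s] == "HOMO6"]
        wt6 = [s for s in study.sample_sheet.samples if study.groups[s] == "WT6"]
        homo6_vals.append(study.gene_counts.data.loc[switch, homo6].to_numpy().ravel())
        wt6_vals.append(study.gene_counts.data.loc[switch, wt6].to_numpy().ravel())
    homo6_vals = np.concatenate(homo6_vals)
    wt6_vals = np.concatenate(wt6_vals)
    assert homo6_vals.size >= 6_000
    # 6-somite is the low state for switch-up genes: mean mu in both genotypes
    assert homo6_vals.mean() == pytest.approx(mu, rel=0.05)
    assert wt6_vals.mean() == pytest.approx(mu, rel=0.05)
    assert wt6_vals.var(ddof=1) == pytest.approx(mu + phi * mu**2, rel=0.15)
    assert homo6_vals.var(ddof=1) == pytest.approx(mu + inflation * phi * mu**2, rel=0.15)


def test_null_design_yields_only_false_positives():
    cfg = SimConfig(
        fractions={},
        n_genes=2000,
        n_repeat_loci=30,
        n_drivers=2,
        passengers_per_driver=3,
        n_independent_de_repeats=4,
        n_tss_dmrs=2,
        seed=9,
    )
    study, truth = simulate_study(cfg)
    assert (truth.genes["compartment_class"] == "null").all()
    counts = filter_expressed(study.gene_counts)
    norm = tmm_factors(counts)
    disp = estimate_dispersion(counts, norm, study.groups)
    res = nb_contrast_test(counts, norm, disp, study.groups, ("WT6", "HOMO6"))
    assert int((res.calls != "ns").sum()) <= 5


def test_write_read_round_trip(tmp_path, small_study):
    study, truth = small_study
    write_study(study, truth, tmp_path)
    study2, truth2 = read_study(tmp_path)
    assert study2.gene_counts.data.equals(study.gene_counts.data)
    assert study2.maternal_counts.data.equals(study.maternal_counts.data)
    assert study2.repeat_annotation.data[["chrom", "start", "end", "name"]].equals(
        study.repeat_annotation.data[["chrom", "start", "end", "name"]]
    )
    assert truth2.genes["compartment_class"].equals(truth.genes["compartment_class"])
    assert truth2.repeats.equals(truth.repeats)
    pd.testing.assert_frame_equal(study2.methylation, study.methylation, atol=1e-9)


def test_empty_repeat_annotation_round_trip(tmp_path):
    from stagematch.io import FeatureAnnotation, read_bed, write_bed

    empty = FeatureAnnotation(
        pd.DataFrame(
            columns=["chrom", "start", "end", "name", "score", "strand", "subfamily", "family"]
        ).astype({"start": np.int64, "end": np.int64})
    )
    p = tmp_path / "empty.bed"
    write_bed(empty, p)
    assert len(read_bed(p)) == 0
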