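import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from stagematch import (
    ContrastResults,
    bh_adjust,
    call_de,
    cpm,
    estimate_dispersion,
    filter_expressed,
    nb_contrast_test,
    tmm_factors,
)
from conftest import count_matrix, nb_counts
from oracles import bh_reference, tmm_reference


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def test_tmm_identical_columns_give_unit_factors():
    cm = count_matrix(np.tile([[10], [50], [200], [5]], (1, 3)))
    nf = tmm_factors(cm)
    assert np.allclose(nf.factors, 1.0)


def test_tmm_doubled_library_equalizes_cpm():
    rng = np.random.default_rng(0)
    col = rng.negative_binomial(5, 0.05, 200)
    cm = count_matrix(np.column_stack([col, 2 * col]))
    nf = tmm_factors(cm)
    c = cpm(cm, nf)
    assert np.allclose(c["s0"], c["s1"])


def test_tmm_single_shared_gene_gives_unit_factors():
    cm = count_matrix([[100, 250, 90]])
    assert np.allclose(tmm_factors(cm).factors, 1.0)


@pytest.mark.parametrize("seed", range(5))
def test_tmm_matches_bruteforce_reference(seed):
    rng = np.random.default_rng(seed)
    x = rng.negative_binomial(5, 0.02, size=(50, 6))
    x[rng.random(x.shape) < 0.1] = 0
    cm = count_matrix(x)
    ours = tmm_factors(cm).factors.to_numpy()
    ref = tmm_reference(x)
    assert np.allclose(ours, ref, atol=1e-8)


def test_tmm_matches_edger(tmp_path):
    """Cross-check against the Bioconductor implementation on one matrix."""
    import subprocess

    rng = np.random.default_rng(7)
    x = rng.negative_binomial(5, 0.02, size=(50, 6))
    cm = count_matrix(x)
    p = tmp_path / "x.tsv"
    cm.data.to_csv(p, sep="\t")
    script = (
        'suppressMessages(library(edgeR));'
        f'x <- as.matrix(read.delim("{p}", row.names=1));'
        'cat(sprintf("%.10f\\n", calcNormFactors(x, method="TMM")))'
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    ref = np.array([float(v) for v in out.stdout.split()])
    assert np.allclose(tmm_factors(cm).factors.to_numpy(), ref, atol=1e-8)


def test_tmm_rejects_zero_library():
    with pytest.raises(ValueError, match="zero total"):
        tmm_factors(count_matrix([[0, 5], [0, 5]]))


# ---------------------------------------------------------------------------
# CPM and filtering
# ---------------------------------------------------------------------------


def test_cpm_arithmetic_and_log_prior():
    cm = count_matrix([[100], [999_900]])
    c = cpm(cm)
    assert c.iloc[0, 0] == pytest.approx(100.0)
    logc = cpm(cm, log=True)
    assert np.isfinite(logc.to_numpy()).all()
    zero = count_matrix([[0, 0], [1000, 1000]])
    assert np.isfinite(cpm(zero, log=True).to_numpy()).all()


def test_cpm_invariant_to_library_scaling():
    rng = np.random.default_rng(1)
    x = rng.poisson(50, size=(100, 2))
    cm1 = count_matrix(x)
    cm2 = count_matrix(np.column_stack([x[:, 0], x[:, 1] * 3]))
    c1 = cpm(cm1)
    c2 = cpm(cm2)
    assert np.allclose(c1["s1"], c2["s1"])


def test_filter_expressed_boundaries():
    # CPM per sample is count/libsize*1e6; construct exact CPMs with 1e6 libraries
    filler = 1_000_000
    counts = np.array(
        [
            [1, 0, 2, 0],  # CPM 1.5, 0.2, 2.1, 0.0 scaled below -> retained
            [0, 0, 0, 0],  # all zero -> removed
            [2, 0, 0, 0],  # CPM > 1 in exactly one sample -> removed
        ]
    )
    # craft libraries of ~2/3 mio so counts 1 and 2 give CPM 1.5 / 2.1 etc.
    lib_targets = np.array([1 / 1.5, 1 / 1.05, 2 / 2.1, 1.0]) * 1e6
    pad = np.round(lib_targets - counts.sum(axis=0)).astype(int)
    x = np.vstack([counts, np.diag(pad)])
    cm = count_matrix(x)
    kept = filter_expressed(cm, cpm_min=1.0, min_samples=2)
    assert "g0" in kept.features
    assert "g1" not in kept.features
    assert "g2" not in kept.features


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------


def test_bh_hand_computed_examples():
    assert np.allclose(bh_adjust(pd.Series([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])
    assert bh_adjust(pd.Series([0.04]))[0] == pytest.approx(0.04)
    assert (bh_adjust(pd.Series([1.0, 1.0, 1.0])) == 1.0).all()


def test_bh_propagates_na():
    q = bh_adjust(pd.Series([0.01, np.nan, 0.5]))
    assert np.isnan(q[1])
    assert np.allclose(q[[0, 2]], bh_reference([0.01, 0.5]))


@given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=200))
def test_bh_matches_bruteforce(pvals):
    ours = bh_adjust(pd.Series(pvals)).to_numpy()
    assert np.allclose(ours, bh_reference(pvals), atol=1e-12)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


def _two_group_series(n):
    return pd.Series(["A"] * n + ["B"] * n, index=[f"s{j}" for j in range(2 * n)])


def test_dispersion_poisson_data_near_zero():
    rng = np.random.default_rng(2)
    libs = np.full(8, 1e6)
    y = rng.poisson(np.full((2000, 8), 100.0))
    cm = count_matrix(y)
    nf = tmm_factors(cm)
    disp = estimate_dispersion(cm, nf, _two_group_series(4))
    assert np.median(disp.shrunken) <= 0.01


def test_dispersion_recovers_planted_level():
    rng = np.random.default_rng(3)
    libs = np.exp(rng.normal(np.log(1e6), 0.1, 8))
    y = nb_counts(rng, np.full((2000, 8), 200.0), np.full((2000, 1), 0.4), libs)
    cm = count_matrix(y)
    nf = tmm_factors(cm)
    disp = estimate_dispersion(cm, nf, _two_group_series(4))
    assert 0.25 <= np.median(disp.shrunken) <= 0.6


def test_dispersion_constant_counts_floored():
    cm = count_matrix(np.full((5, 6), 7))
    nf_lib = cm.data.sum()
    from stagematch import NormFactors

    nf = NormFactors(nf_lib.astype(float), pd.Series(1.0, index=cm.samples))
    disp = estimate_dispersion(cm, nf, _two_group_series(3))
    assert np.isfinite(disp.shrunken).all()
    assert (disp.shrunken >= 1e-8).all()


# ---------------------------------------------------------------------------
# NB contrast test
# ---------------------------------------------------------------------------


def _run_contrast(y, n, contrast=("A", "B"), **kw):
    cm = count_matrix(y)
    groups = _two_group_series(n)
    cmf = filter_expressed(cm)
    nf = tmm_factors(cmf)
    disp = estimate_dispersion(cmf, nf, groups)
    return nb_contrast_test(cmf, nf, disp, groups, contrast, **kw)


def test_null_type_one_error_is_calibrated():
    fracs = []
    for seed in (1, 2, 3):
        rng = np.random.default_rng(seed)
        base = np.exp(rng.normal(np.log(50), 1.0, 2000)).clip(1, 3000)
        phi = rng.gamma(2.0, 0.025, 2000).clip(1e-3)
        libs = np.exp(rng.normal(np.log(1e6), 0.1, 8))
        y = nb_counts(rng, np.repeat(base[:, None], 8, 1), phi[:, None], libs)
        res = _run_contrast(y, 4)
        p = res.table["pvalue"].dropna()
        fracs.append(float(np.mean(p < 0.05)))
    assert 0.03 <= np.mean(fracs) <= 0.07


def test_power_at_planted_fourfold_change():
    rng = np.random.default_rng(5)
    base = np.exp(rng.normal(np.log(50), 1.0, 2000)).clip(1, 3000)
    base[:200] = 100.0
    phi = rng.gamma(2.0, 0.025, 2000).clip(1e-3)
    phi[:200] = 0.1
    libs = np.exp(rng.normal(np.log(1e6), 0.1, 8))
    mu = np.repeat(base[:, None], 8, 1)
    mu[:200, :4] *= 4.0  # log2FC = 2 in group A
    y = nb_counts(rng, mu, phi[:, None], libs)
    res = _run_contrast(y, 4)
    power = float((res.table.iloc[:200]["call"] == "up").mean())
    assert power >= 0.8


def test_all_zero_feature_gets_na_p():
    rng = np.random.default_rng(6)
    y = rng.poisson(50, size=(50, 8))
    y[0] = 0
    cm = count_matrix(y)
    nf = tmm_factors(cm)
    groups = _two_group_series(4)
    disp = estimate_dispersion(cm, nf, groups)
    res = nb_contrast_test(cm, nf, disp, groups, ("A", "B"))
    assert np.isnan(res.table.loc["g0", "pvalue"])
    assert res.n_untested == 1


def test_log2fc_antisymmetry_under_contrast_swap():
    rng = np.random.default_rng(8)
    y = rng.poisson(rng.uniform(5, 500, size=(100, 1)) * np.ones((1, 8))).astype(int)
    cm = count_matrix(y)
    nf = tmm_factors(cm)
    groups = _two_group_series(4)
    disp = estimate_dispersion(cm, nf, groups)
    ab = nb_contrast_test(cm, nf, disp, groups, ("A", "B"))
    ba = nb_contrast_test(cm, nf, disp, groups, ("B", "A"))
    assert np.allclose(ab.table["log2fc"], -ba.table["log2fc"], atol=1e-6)
    assert np.allclose(ab.table["pvalue"], ba.table["pvalue"], equal_nan=True, atol=1e-10)


def test_de_call_thresholds():
    table = pd.DataFrame(
        {
            "log2fc": [1.3, 1.0, 3.0, -1.5],
            "pvalue": [1e-3] * 4,
            "qvalue": [0.04, 0.04, 0.06, 0.01],
            "mean_cpm_a": 1.0,
            "mean_cpm_b": 1.0,
            "call": "ns",
        },
        index=list("wxyz"),
    )
    res = call_de(ContrastResults(("A", "B"), table))
    assert list(res.table["call"]) == ["up", "ns", "ns", "down"]
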