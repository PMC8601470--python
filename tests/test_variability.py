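import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stagematch import (
    DispersionContrast,
    diff_dispersion_test,
    group_cv,
    pca_scatter,
    sample_clustering,
    tmm_factors,
    top_dispersed,
    vst_transform,
)
from conftest import count_matrix, nb_counts


def _groups(n, labels=("A", "B")):
    return pd.Series(
        [labels[0]] * n + [labels[1]] * n, index=[f"s{j}" for j in range(2 * n)]
    )


# ---------------------------------------------------------------------------
# VST
# ---------------------------------------------------------------------------


def test_vst_finite_at_zero_and_scale_invariant():
    cm = count_matrix([[0, 10], [100, 100]])
    v = vst_transform(cm, alpha=0.1)
    assert np.isfinite(v.data.to_numpy()).all()
    # doubling a count and its size factor leaves y unchanged
    x, s, alpha = 40.0, 1.0, 0.1
    y1 = np.log2(x / s + 1 / (2 * alpha))
    y2 = np.log2(2 * x / (2 * s) + 1 / (2 * alpha))
    assert y1 == pytest.approx(y2)


def test_vst_stabilizes_variance_across_mean_range():
    rng = np.random.default_rng(0)
    alpha = 0.1
    means = np.repeat(np.geomspace(20, 2000, 30), 200)
    libs = np.full(20, 1e6)
    y = nb_counts(rng, np.repeat(means[:, None], 20, 1), np.full((means.size, 1), alpha), libs)
    v = vst_transform(count_matrix(y), alpha=alpha)
    sd = v.data.std(axis=1, ddof=1)
    mean = v.data.mean(axis=1)
    slope = np.polyfit(mean, sd, 1)[0]
    assert abs(slope) < 0.1


# ---------------------------------------------------------------------------
# CV
# ---------------------------------------------------------------------------


def test_cv_zero_for_identical_replicates_and_scale_invariant():
    data = pd.DataFrame(
        np.tile(np.arange(1.0, 6.0)[:, None], (1, 4)),
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{j}" for j in range(4)],
    )
    mean_cv, per_gene = group_cv(data, _groups(2))
    assert np.allclose(mean_cv, 0.0)
    rng = np.random.default_rng(1)
    data2 = pd.DataFrame(rng.normal(10, 1, (20, 6)), columns=[f"s{j}" for j in range(6)])
    cv1, _ = group_cv(data2, _groups(3))
    cv2, _ = group_cv(data2 * 3.0, _groups(3))
    # scaling all values by c > 0 leaves the CV unchanged (shift co-scales)
    assert np.allclose(cv1, cv2, atol=1e-12)


def test_cv_requires_replicates():
    data = pd.DataFrame(np.ones((3, 3)), columns=["s0", "s1", "s2"])
    groups = pd.Series(["A", "A", "B"], index=data.columns)
    with pytest.raises(ValueError, match="fewer than 2"):
        group_cv(data, groups)


def test_cv_flags_inflated_group():
    rng = np.random.default_rng(2)
    tight = rng.normal(10, 0.3, (100, 4))
    noisy = rng.normal(10, 1.5, (100, 4))
    data = pd.DataFrame(np.hstack([tight, noisy]), columns=[f"s{j}" for j in range(8)])
    mean_cv, _ = group_cv(data, _groups(4))
    assert mean_cv["B"] > mean_cv["A"]


# ---------------------------------------------------------------------------
# PCA scatter
# ---------------------------------------------------------------------------


def test_pca_duplicated_samples_scatter_zero():
    rng = np.random.default_rng(3)
    col = rng.normal(size=50)
    data = pd.DataFrame(
        np.column_stack([col, col, rng.normal(size=50), rng.normal(size=50)]),
        index=[f"g{i}" for i in range(50)],
        columns=["a1", "a2", "b1", "b2"],
    )
    groups = pd.Series(["A", "A", "B", "B"], index=data.columns)
    out = pca_scatter(data, data.index, groups)
    assert out.scatter["A"] == pytest.approx(0.0, abs=1e-8)
    assert out.scatter["B"] > 0


def test_pca_invariant_to_feature_order():
    rng = np.random.default_rng(4)
    data = pd.DataFrame(
        rng.normal(size=(30, 6)), index=[f"g{i}" for i in range(30)],
        columns=[f"s{j}" for j in range(6)],
    )
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=data.columns)
    a = pca_scatter(data, data.index, groups)
    b = pca_scatter(data.iloc[::-1], data.index, groups)
    assert np.allclose(np.abs(a.coordinates), np.abs(b.coordinates), atol=1e-8)
    assert np.allclose(a.scatter, b.scatter, atol=1e-8)


# ---------------------------------------------------------------------------
# sample clustering
# ---------------------------------------------------------------------------


def test_clustering_distances_symmetric_zero_diagonal():
    rng = np.random.default_rng(5)
    data = pd.DataFrame(rng.normal(size=(40, 6)), columns=[f"s{j}" for j in range(6)])
    out = sample_clustering(data)
    d = out.distances.to_numpy()
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0.0)
    dup = data.copy()
    dup["s1"] = dup["s0"]
    assert sample_clustering(dup).distances.loc["s0", "s1"] == pytest.approx(0.0)


def test_clustering_top_split_separates_genotypes():
    """A genotype effect much larger than the stage effect splits WT from mutant first."""
    rng = np.random.default_rng(6)
    n_genes = 200
    base = rng.normal(8, 1, n_genes)
    cols, names = [], []
    for geno in ("WT", "HOMO"):
        for stage in ("6", "12"):
            for r in range(2):
                shift = (geno == "HOMO") * 3.0 + (stage == "12") * 0.5
                cols.append(base + shift + rng.normal(0, 0.2, n_genes))
                names.append(f"{geno}{stage}_{r}")
    data = pd.DataFrame(np.column_stack(cols), columns=names)
    out = sample_clustering(data)
    a, b = out.top_split()
    genos = {tuple(sorted({n.startswith("HOMO") for n in side})) for side in (a, b)}
    assert genos == {(True,), (False,)}


# ---------------------------------------------------------------------------
# differential dispersion
# ---------------------------------------------------------------------------


def test_dispersion_null_type_one_in_band():
    rng = np.random.default_rng(7)
    libs = np.exp(rng.normal(np.log(1e6), 0.1, 8))
    y = nb_counts(rng, np.full((2000, 8), 100.0), np.full((2000, 1), 0.1), libs)
    res = diff_dispersion_test(count_matrix(y), tmm_factors(count_matrix(y)), _groups(4), ("B", "A"))
    frac = float((res.table["pvalue"].dropna() < 0.05).mean())
    assert 0.02 <= frac <= 0.08


def test_dispersion_estimates_recover_inflation():
    rng = np.random.default_rng(8)
    libs = np.full(16, 1e6)
    phi = np.full((500, 16), 0.1)
    phi[:, 8:] *= 4.0
    y = nb_counts(rng, np.full((500, 16), 200.0), phi, libs)
    res = diff_dispersion_test(count_matrix(y), tmm_factors(count_matrix(y)), _groups(8), ("B", "A"))
    # estimator bias: mean log-dispersion ratio within 0.2 nats of ln(4)
    est = np.log(2.0) * res.table["dispersion_log2fc"].mean()
    assert abs(est - np.log(4.0)) < 0.2


def test_dispersion_call_requires_both_q_and_logfc():
    rng = np.random.default_rng(9)
    y = nb_counts(rng, np.full((100, 8), 100.0), np.full((100, 1), 0.1), np.full(8, 1e6))
    cm = count_matrix(y)
    res = DispersionContrast(cm, _groups(4), ("B", "A")).fit()
    t = res.table.copy()
    # force a significant q with sub-threshold fold change: must remain ns
    t.loc["g0", ["qvalue", "dispersion_log2fc"]] = [0.01, 1.0]
    sig = (t["qvalue"] < res.q_max) & t["pvalue"].notna()
    call = np.where(sig & (t["dispersion_log2fc"].abs() > res.min_abs_log2fc), "called", "ns")
    assert call[0] == "ns"


def test_dispersion_antisymmetry_under_label_swap():
    rng = np.random.default_rng(10)
    phi = np.full((200, 8), 0.1)
    phi[:50, 4:] *= 6.0
    y = nb_counts(rng, np.full((200, 8), 150.0), phi, np.full(8, 1e6))
    cm = count_matrix(y)
    nf = tmm_factors(cm)
    ab = diff_dispersion_test(cm, nf, _groups(4), ("A", "B"))
    ba = diff_dispersion_test(cm, nf, _groups(4), ("B", "A"))
    assert np.allclose(
        ab.table["dispersion_log2fc"], -ba.table["dispersion_log2fc"], atol=1e-6
    )
    assert np.allclose(ab.table["lrt"], ba.table["lrt"], atol=1e-6)


def test_top_dispersed_ordering_and_enrichment():
    rng = np.random.default_rng(11)
    phi = np.full((400, 8), 0.05)
    inflated = set(range(40))
    phi[:40, 4:] *= 10.0
    y = nb_counts(rng, np.full((400, 8), 300.0), phi, np.full(8, 1e6))
    cm = count_matrix(y)
    nf = tmm_factors(cm)
    res = diff_dispersion_test(cm, nf, _groups(4), ("B", "A"))
    vst = vst_transform(cm, nf)
    top, z = top_dispersed(res, vst, k=0)
    assert top == []
    top_all, _ = top_dispersed(res, vst, k=400)
    assert len(top_all) == 400
    stats_sorted = res.table.loc[top_all, "lrt"]
    assert (stats_sorted.to_numpy()[:-1] >= stats_sorted.to_numpy()[1:] - 1e-9).all()
    top50, z50 = top_dispersed(res, vst, k=50)
    hits = sum(1 for g in top50 if int(g[1:]) in inflated)
    p = stats.hypergeom.sf(hits - 1, 400, 40, 50)
    assert p < 0.01
    assert z50.shape[1] == 8
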