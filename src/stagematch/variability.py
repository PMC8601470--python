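"""Group-wise transcriptional variability: VST, CV, PCA scatter, clustering,
and a differential-dispersion (differential-variability) test.

The central question is not which genes change in mean but which genes become
*noisier* in the mutant: developmentally delayed 6-somite mutants show
embryo-to-embryo scatter at genes that switch expression programs between the
6- and 12-somite stages.  Variability is quantified three ways — per-gene
coefficients of variation on variance-stabilized counts, scatter of replicate
samples in principal-component space, and a per-gene likelihood-ratio test on
the NB dispersion with the mean profiled out.  A gene is called
differentially variable at BH-adjusted dispersion FDR < 0.05 and a
dispersion |log2 fold change| > 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .de import (
    CountMatrix,
    DispersionEstimates,
    NormFactors,
    PHI_FLOOR,
    bh_adjust,
    estimate_dispersion,
    fit_group_abundance,
    nb_loglik,
    tmm_factors,
)

__all__ = [
    "VSTMatrix",
    "DispersionResults",
    "DispersionContrast",
    "vst_transform",
    "group_cv",
    "pca_scatter",
    "sample_clustering",
    "diff_dispersion_test",
    "top_dispersed",
]

DISPERSION_Q_MAX = 0.05
DISPERSION_MIN_ABS_LOG2FC = 1.5


# ---------------------------------------------------------------------------
# variance stabilization
# ---------------------------------------------------------------------------


@dataclass
class VSTMatrix:
    """Variance-stabilized expression: ``y = log2(x/s + 1/(2 alpha))``.

    ``s`` are effective-library size factors scaled to geometric mean 1 and
    ``alpha`` a single trended NB dispersion, so that for counts with
    ``var = mu + alpha mu^2`` the transform's variance is approximately
    mean-independent; for ``alpha -> 0`` it reduces to a shifted log2.
    """

    data: pd.DataFrame
    alpha: float
    size_factors: pd.Series = field(repr=False)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def vst_transform(
    counts: CountMatrix,
    norm: NormFactors | None = None,
    dispersion: DispersionEstimates | None = None,
    alpha: float | None = None,
) -> VSTMatrix:
    """Closed-form NB variance-stabilizing transform of a count matrix."""
    if norm is None:
        norm = tmm_factors(counts)
    eff = norm.effective[counts.samples].to_numpy().astype(float)
    s = eff / np.exp(np.mean(np.log(eff)))
    if alpha is None:
        if dispersion is not None:
            alpha = float(np.median(dispersion.trended))
        else:
            alpha = 0.1
    alpha = max(alpha, PHI_FLOOR)
    y = np.log2(counts.values.astype(float) / s + 1.0 / (2.0 * alpha))
    return VSTMatrix(
        data=pd.DataFrame(y, index=counts.features, columns=counts.samples),
        alpha=alpha,
        size_factors=pd.Series(s, index=pd.Index(counts.samples, name="sample")),
    )


def group_cv(
    vst: VSTMatrix | pd.DataFrame,
    groups: pd.Series,
    feature_set=None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-group mean coefficient of variation over a feature set.

    Values are shifted above zero by the minimum of the *full* matrix plus 1%
    of its range, before any feature subsetting: the shift co-scales with the
    data (CV exactly invariant to rescaling) and is identical for every
    feature set, so compartment CVs share one scale.  Per gene CV = sd/mean
    across the group's replicates; the group-level value is the mean over
    genes.  Returns (per-group mean CV, per-gene CV table).
    """
    data = vst.data if isinstance(vst, VSTMatrix) else vst
    lo, hi = float(data.to_numpy().min()), float(data.to_numpy().max())
    shift = -lo + (0.01 * (hi - lo) if hi > lo else 1.0)
    if feature_set is not None:
        feats = pd.Index(feature_set)
        data = data.loc[data.index.intersection(feats)]
    if data.empty:
        raise ValueError("empty feature set")
    shifted = data + shift
    groups = groups[data.columns]
    per_gene = {}
    for g in pd.unique(groups.to_numpy()):
        cols = groups.index[groups == g]
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
        sub = shifted[cols]
        per_gene[g] = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    table = pd.DataFrame(per_gene)
    return table.mean(axis=0), table


@dataclass
class PCAScatter:
    coordinates: pd.DataFrame  # samples x (PC1, PC2)
    scatter: pd.Series  # per-group mean pairwise distance in PC space
    explained_variance_ratio: np.ndarray


def pca_scatter(
    log2cpm: pd.DataFrame,
    feature_set,
    groups: pd.Series,
    n_components: int = 2,
    scale: bool = False,
) -> PCAScatter:
    """PCA of samples on a feature subset plus per-group scatter scores.

    Samples are observations; features are centered (and optionally unit
    scaled).  The scatter score of a group is the mean pairwise Euclidean
    distance among its samples in the first two components — tight replicate
    groups score near zero, heterogeneous ones score high.
    """
    feats = pd.Index(feature_set)
    sub = log2cpm.loc[log2cpm.index.intersection(feats)]
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 features for PCA")
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA")
    x = sub.to_numpy().T  # samples x features
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / np.where(sd > 0, sd, 1.0)
    n_components = min(n_components, min(x.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    coord_df = pd.DataFrame(
        coords[:, :2],
        index=sub.columns,
        columns=["PC1", "PC2"][: coords.shape[1]],
    )
    groups = groups[coord_df.index]
    scatter = {}
    for g in pd.unique(groups.to_numpy()):
        pts = coord_df.loc[groups.index[groups == g]].to_numpy()
        if pts.shape[0] < 2:
            scatter[g] = np.nan
            continue
        scatter[g] = float(np.mean(pdist(pts)))
    return PCAScatter(
        coordinates=coord_df,
        scatter=pd.Series(scatter),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


@dataclass
class SampleClustering:
    distances: pd.DataFrame
    linkage: np.ndarray = field(repr=False)
    order: list[str] = field(default_factory=list)

    def top_split(self) -> tuple[set[str], set[str]]:
        """The two sample sets produced by cutting the dendrogram's root."""
        labels = hierarchy.fcluster(self.linkage, t=2, criterion="maxclust")
        samples = list(self.distances.index)
        a = {s for s, l in zip(samples, labels) if l == 1}
        b = {s for s, l in zip(samples, labels) if l == 2}
        return a, b


def sample_clustering(log2cpm: pd.DataFrame, feature_set=None) -> SampleClustering:
    """Euclidean distances between samples on a feature subset, average linkage.

    Samples are ordered by id before clustering so ties break
    deterministically.
    """
    data = log2cpm
    if feature_set is not None:
        feats = pd.Index(feature_set)
        data = data.loc[data.index.intersection(feats)]
    samples = sorted(data.columns)
    x = data[samples].to_numpy().T
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    d = pdist(x, metric="euclidean")
    z = hierarchy.linkage(d, method="average")
    order = [samples[i] for i in hierarchy.leaves_list(z)]
    dist_df = pd.DataFrame(squareform(d), index=samples, columns=samples)
    return SampleClustering(distances=dist_df, linkage=z, order=order)


# ---------------------------------------------------------------------------
# differential dispersion
# ---------------------------------------------------------------------------

_LOG_PHI_BOUNDS = (np.log(1e-6), np.log(50.0))
_GOLDEN = 0.5 * (np.sqrt(5.0) - 1.0)


def _profile_apl(
    y_groups: list[np.ndarray],
    lib_groups: list[np.ndarray],
    log_phi: np.ndarray,
    cox_reid: bool = True,
) -> np.ndarray:
    """Per-gene adjusted profile log-likelihood at a common dispersion.

    Group means are profiled out by the Newton solver; the Cox-Reid term
    corrects for their estimation, which otherwise biases dispersion MLEs
    down at small replicate numbers.
    """
    phi = np.exp(log_phi)
    apl = np.zeros(phi.shape[0])
    for yg, lg in zip(y_groups, lib_groups):
        lam = fit_group_abundance(yg, lg, phi)
        mu = lam[:, None] * lg[None, :]
        apl += nb_loglik(yg, mu, phi)
        if cox_reid:
            w = np.sum(mu / (1.0 + phi[:, None] * mu), axis=1)
            apl -= 0.5 * np.log(np.clip(w, 1e-10, None))
    return apl


def _maximize_log_phi(
    y_groups: list[np.ndarray],
    lib_groups: list[np.ndarray],
    n_genes: int,
    cox_reid: bool = True,
    n_iter: int = 35,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized golden-section maximization of the profile APL over log phi.

    The profile likelihood in the dispersion is unimodal for NB data (the
    maximum may sit at the lower bound for underdispersed genes), so golden
    section is reliable without derivatives.  Returns (log_phi_hat, apl_hat).
    """
    lo = np.full(n_genes, _LOG_PHI_BOUNDS[0])
    hi = np.full(n_genes, _LOG_PHI_BOUNDS[1])
    for _ in range(n_iter):
        x1 = hi - _GOLDEN * (hi - lo)
        x2 = lo + _GOLDEN * (hi - lo)
        f1 = _profile_apl(y_groups, lib_groups, x1, cox_reid)
        f2 = _profile_apl(y_groups, lib_groups, x2, cox_reid)
        move_right = f1 < f2  # maximum lies in [x1, hi]
        lo = np.where(move_right, x1, lo)
        hi = np.where(move_right, hi, x2)
    best = 0.5 * (lo + hi)
    fbest = _profile_apl(y_groups, lib_groups, best, cox_reid)
    return best, fbest


@dataclass
class DispersionResults:
    """Differential-dispersion test results for one two-group comparison.

    ``table`` columns: dispersion_log2fc (positive = more dispersed in the
    first-named group), mean_log2fc, phi_a, phi_b, lrt, pvalue, qvalue, call.
    """

    contrast: tuple[str, str]
    table: pd.DataFrame
    q_max: float = DISPERSION_Q_MAX
    min_abs_log2fc: float = DISPERSION_MIN_ABS_LOG2FC

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]

    def called_features(self) -> pd.Index:
        return self.table.index[self.table["call"] != "ns"]

    def summary(self) -> str:
        a, b = self.contrast
        n_called = int((self.table["call"] != "ns").sum())
        return "\n".join(
            [
                f"differential dispersion {a} vs {b}",
                f"  features tested: {int(self.table['pvalue'].notna().sum())}"
                f" of {len(self.table)}",
                f"  thresholds: q < {self.q_max}, |dispersion log2FC| > {self.min_abs_log2fc}",
                f"  differentially variable: {n_called}",
            ]
        )


class DispersionContrast:
    """Two-group NB model with group effects in both the mean and the dispersion.

    ``log mu = b0 + b1 * group`` and ``log phi = g0 + g1 * group`` with
    log effective-library offsets; the mean parameters are profiled out and
    ``g1 = 0`` is tested by an (adjusted) likelihood-ratio test against
    chi-square(1).  Because mean and dispersion parameters separate by group,
    the full model reduces to independent per-group fits and the null to a
    common-dispersion fit, each a one-dimensional search.

        res = DispersionContrast(counts, groups, ("MATMUT6", "MATWT6")).fit()
    """

    def __init__(
        self,
        counts: CountMatrix,
        groups: pd.Series,
        contrast: tuple[str, str],
        norm: NormFactors | None = None,
        cox_reid: bool = True,
    ) -> None:
        a, b = contrast
        groups = groups[counts.samples]
        samples_a = [s for s in counts.samples if groups[s] == a]
        samples_b = [s for s in counts.samples if groups[s] == b]
        if len(samples_a) < 2 or len(samples_b) < 2:
            raise ValueError(f"contrast {a} vs {b}: both groups need >= 2 samples")
        self.contrast = (a, b)
        self.counts = counts.subset(samples=samples_a + samples_b)
        self.samples_a = samples_a
        self.samples_b = samples_b
        self.cox_reid = cox_reid
        if norm is None:
            norm = tmm_factors(self.counts)
        else:
            norm = norm.reindex(self.counts.samples)
        self.norm = norm

    def fit(
        self,
        q_max: float = DISPERSION_Q_MAX,
        min_abs_log2fc: float = DISPERSION_MIN_ABS_LOG2FC,
    ) -> DispersionResults:
        y = self.counts.values.astype(float)
        eff = self.norm.effective[self.counts.samples].to_numpy()
        in_a = np.array([s in set(self.samples_a) for s in self.counts.samples])
        ya, yb = y[:, in_a], y[:, ~in_a]
        na, nb = eff[in_a], eff[~in_a]
        n_genes = y.shape[0]

        log_phi_a, apl_a = _maximize_log_phi([ya], [na], n_genes, self.cox_reid)
        log_phi_b, apl_b = _maximize_log_phi([yb], [nb], n_genes, self.cox_reid)
        log_phi_0, apl_0 = _maximize_log_phi([ya, yb], [na, nb], n_genes, self.cox_reid)

        lrt = np.clip(2.0 * (apl_a + apl_b - apl_0), 0.0, None)
        pvals = stats.chi2.sf(lrt, df=1)
        # dispersion is unidentifiable without variation in both groups
        untestable = (ya.sum(axis=1) == 0) | (yb.sum(axis=1) == 0)
        pvals = np.where(untestable, np.nan, pvals)

        lam_a = fit_group_abundance(ya, na, np.exp(log_phi_a))
        lam_b = fit_group_abundance(yb, nb, np.exp(log_phi_b))
        prior = 0.5 / eff.mean()
        mean_log2fc = np.log2((lam_a + prior) / (lam_b + prior))
        disp_log2fc = (log_phi_a - log_phi_b) / np.log(2.0)

        qvals = bh_adjust(pd.Series(pvals, index=self.counts.features)).to_numpy()
        sig = (qvals < q_max) & ~np.isnan(pvals)
        call = np.where(
            sig & (disp_log2fc > min_abs_log2fc),
            "up",
            np.where(sig & (disp_log2fc < -min_abs_log2fc), "down", "ns"),
        )
        table = pd.DataFrame(
            {
                "dispersion_log2fc": disp_log2fc,
                "mean_log2fc": mean_log2fc,
                "phi_a": np.exp(log_phi_a),
                "phi_b": np.exp(log_phi_b),
                "lrt": lrt,
                "pvalue": pvals,
                "qvalue": qvals,
                "call": call,
            },
            index=self.counts.features,
        )
        return DispersionResults(
            contrast=self.contrast, table=table, q_max=q_max, min_abs_log2fc=min_abs_log2fc
        )


def diff_dispersion_test(
    counts: CountMatrix,
    norm: NormFactors,
    groups: pd.Series,
    contrast: tuple[str, str],
    q_max: float = DISPERSION_Q_MAX,
    min_abs_log2fc: float = DISPERSION_MIN_ABS_LOG2FC,
) -> DispersionResults:
    """Fit the double NB GLM and call differentially variable features."""
    model = DispersionContrast(counts, groups, contrast, norm=norm)
    return model.fit(q_max=q_max, min_abs_log2fc=min_abs_log2fc)


def top_dispersed(
    result: DispersionResults,
    vst: VSTMatrix,
    k: int = 500,
) -> tuple[list[str], pd.DataFrame]:
    """Top-k features by dispersion LRT statistic, with z-scores over all samples.

    Mirrors the heatmap view of the most variable transcripts: per-gene
    z-scores of variance-stabilized values across the full sample set, rows
    ordered by the test statistic.
    """
    stat = result.table["lrt"].copy()
    stat[result.table["pvalue"].isna()] = -np.inf
    order = stat.sort_values(ascending=False, kind="mergesort").index
    top = [f for f in order[: max(k, 0)]]
    sub = vst.data.loc[vst.data.index.intersection(pd.Index(top))].loc[
        [f for f in top if f in vst.data.index]
    ]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1).replace(0.0, np.nan)
    z = sub.sub(mean, axis=0).div(sd, axis=0).fillna(0.0)
    return top, z
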