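"""Allele-resolved expression ratios and parental-allele derepression classes.

In reciprocal-cross hybrids every transcript can be assigned to the maternal
or paternal allele at strain SNPs (the assignment itself is upstream; this
module consumes the two allele count matrices).  For embryos from oocytes
lacking the maternal factor, variable transcripts are classified by which
parental allele responds: derepression restricted to the maternal allele
(including imprinted genes whose paternal copy stays silent), both alleles
with a maternal bias, and so on.  Classes are defined by per-allele CPM fold
changes between mutant and control groups with declared thresholds — an
allele counts as derepressed at fold change >= ``fc_min`` (default 2) and a
bias requires the two allele fold changes to differ by >= ``bias_min``
(default 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import NormFactors
from .io import CountMatrix

__all__ = [
    "ALLELE_CLASSES",
    "AlleleProfile",
    "allelic_ratio",
    "classify_allelic_change",
]

ALLELE_CLASSES = [
    "MAT-up",
    "PAT-up",
    "both-up-MAT-bias",
    "both-up-PAT-bias",
    "both-up-no-bias",
    "no-change",
]

MIN_INFORMATIVE_DEFAULT = 10


@dataclass
class AlleleProfile:
    """Per-feature, per-sample allele-resolved expression.

    ``ratio`` is the maternal fraction mat/(mat+pat), NA wherever fewer than
    ``min_informative`` allele-assigned reads support it.  CPMs are scaled by
    the total-library effective sizes, so maternal and paternal CPM are
    directly comparable to each other and across samples.
    """

    maternal_cpm: pd.DataFrame
    paternal_cpm: pd.DataFrame
    ratio: pd.DataFrame
    maternal_counts: pd.DataFrame = field(repr=False)
    paternal_counts: pd.DataFrame = field(repr=False)
    min_informative: int = MIN_INFORMATIVE_DEFAULT


def allelic_ratio(
    maternal: CountMatrix,
    paternal: CountMatrix,
    norm: NormFactors,
    min_informative: int = MIN_INFORMATIVE_DEFAULT,
) -> AlleleProfile:
    """Maternal/paternal CPMs and maternal ratios from matched allele matrices."""
    if list(maternal.samples) != list(paternal.samples) or not maternal.features.equals(
        paternal.features
    ):
        raise ValueError("maternal and paternal matrices must share features and samples")
    eff = norm.effective[maternal.samples].to_numpy().astype(float)
    mat = maternal.values.astype(float)
    pat = paternal.values.astype(float)
    total = mat + pat
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total >= min_informative, mat / total, np.nan)
    idx, cols = maternal.features, maternal.samples
    return AlleleProfile(
        maternal_cpm=pd.DataFrame(mat / eff * 1e6, index=idx, columns=cols),
        paternal_cpm=pd.DataFrame(pat / eff * 1e6, index=idx, columns=cols),
        ratio=pd.DataFrame(ratio, index=idx, columns=cols),
        maternal_counts=maternal.data,
        paternal_counts=paternal.data,
        min_informative=min_informative,
    )


def classify_allelic_change(
    profile: AlleleProfile,
    feature_set,
    groups: pd.Series,
    mutant_group: str,
    control_group: str,
    fc_min: float = 2.0,
    bias_min: float = 2.0,
    prior_cpm: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify pre-selected features by which parental allele is derepressed.

    ``feature_set`` should come from a differential-variability or DE
    selection on the mutant vs control comparison; classification itself is a
    deterministic rule on per-allele mean-CPM fold changes (mutant/control,
    with a prior count to keep silent alleles finite):

    * only the maternal allele up (fold >= fc_min): ``MAT-up`` — e.g. an
      imprinted gene whose maternal copy is derepressed while the paternal
      stays silent;
    * only the paternal allele up: ``PAT-up``;
    * both up and the maternal fold exceeds the paternal by >= bias_min:
      ``both-up-MAT-bias`` (and symmetrically ``both-up-PAT-bias``);
    * both up otherwise: ``both-up-no-bias``;
    * neither: ``no-change``.

    Returns (per-feature table, class proportions over the feature set).
    """
    groups = groups[profile.maternal_cpm.columns]
    mutant_samples = groups.index[groups == mutant_group]
    control_samples = groups.index[groups == control_group]
    if len(control_samples) == 0:
        raise ValueError(f"control group {control_group!r} missing from sample set")
    if len(mutant_samples) == 0:
        raise ValueError(f"mutant group {mutant_group!r} missing from sample set")

    feats = pd.Index(feature_set)
    feats = feats[feats.isin(profile.maternal_cpm.index)]

    def fold(cpm: pd.DataFrame) -> pd.Series:
        mut = cpm.loc[feats, mutant_samples].mean(axis=1) + prior_cpm
        ctl = cpm.loc[feats, control_samples].mean(axis=1) + prior_cpm
        return mut / ctl

    fc_mat = fold(profile.maternal_cpm)
    fc_pat = fold(profile.paternal_cpm)
    mat_up = fc_mat >= fc_min
    pat_up = fc_pat >= fc_min

    classes = pd.Series("no-change", index=feats, name="allele_class")
    classes[mat_up & ~pat_up] = "MAT-up"
    classes[~mat_up & pat_up] = "PAT-up"
    both = mat_up & pat_up
    with np.errstate(divide="ignore", invalid="ignore"):
        mat_bias = fc_mat / fc_pat
    classes[both & (mat_bias >= bias_min)] = "both-up-MAT-bias"
    classes[both & (mat_bias <= 1.0 / bias_min)] = "both-up-PAT-bias"
    classes[both & (mat_bias > 1.0 / bias_min) & (mat_bias < bias_min)] = "both-up-no-bias"

    table = pd.DataFrame(
        {
            "fc_maternal": fc_mat,
            "fc_paternal": fc_pat,
            "allele_class": classes,
        }
    )
    proportions = (
        classes.value_counts(normalize=True)
        .reindex(ALLELE_CLASSES, fill_value=0.0)
        .rename("proportion")
    )
    return table, proportions
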