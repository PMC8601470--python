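"""Synthetic stage-matched studies with planted ground truth.

The generator emulates the statistical structure the analysis assumes: NB
gene counts under a WT/HOMO x 6-/12-somite factorial design (plus a
maternal-mutant arm at the 6-somite stage), allele-resolved counts with
per-embryo random derepression of the maternal allele, a toy two-chromosome
genome carrying repeat loci with planted driver/passenger read-through
clusters, hypomethylated driver DMRs and promoter DMRs of at least 12 CpGs,
and stranded coverage tracks that are unidirectional over planted clusters.
Every planted property is recorded in a machine-readable truth table for
recovery testing.

Planted gene classes (``fractions``):

* ``normal-both-up`` / ``normal-both-down`` — expressed higher/lower in the
  wild type than the mutant at both somite stages ("what it takes to be
  normal"); maternal-arm embryos, being genetically wild type, follow the
  WT state.
* ``stage-switch-up`` / ``stage-switch-down`` — change between the 6- and
  12-somite stages in both genotypes ("what it takes to develop").
* ``ehmt2-switch-up`` / ``ehmt2-switch-down`` — same stage switch, but with
  the NB dispersion inflated in the 6-somite mutant: the switch exists in
  the mutant yet is executed noisily, which is what pushes these genes out
  of the mutant's stage contrast.
* ``variance-inflated-only`` — no mean change anywhere, dispersion inflated
  in the 6-somite mutant.

All randomness flows through one seeded generator; a fixed seed gives
bit-identical studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    FeatureAnnotation,
    SampleSheet,
    read_bed,
    read_bedgraph,
    read_counts,
    read_methylation,
    read_sample_sheet,
    write_bed,
    write_bedgraph,
    write_counts,
    write_methylation,
    write_sample_sheet,
)

__all__ = [
    "GENE_CLASSES",
    "ALLELE_TRUTH_CLASSES",
    "SimConfig",
    "SimulatedStudy",
    "TruthTable",
    "simulate_study",
    "write_study",
    "read_study",
]

DEFAULT_GROUPS = ("WT6", "HOMO6", "WT12", "HOMO12", "MATWT6", "MATMUT6")

GENE_CLASSES = [
    "normal-both-up",
    "normal-both-down",
    "stage-switch-up",
    "stage-switch-down",
    "ehmt2-switch-up",
    "ehmt2-switch-down",
    "variance-inflated-only",
    "null",
]

# classes whose HOMO6 dispersion is inflated under the default scope
DEFAULT_INFLATED_CLASSES = (
    "ehmt2-switch-up",
    "ehmt2-switch-down",
    "variance-inflated-only",
)

ALLELE_TRUTH_CLASSES = [
    "biallelic",
    "imprinted-MAT-silent",
    "MAT-derepressed",
    "both-derepressed-MAT-bias",
]

EXPECTED_COMPARTMENT = {
    "normal-both-up": ("normal-both-stages", "up"),
    "normal-both-down": ("normal-both-stages", "down"),
    "stage-switch-up": ("develop-shared", "up"),
    "stage-switch-down": ("develop-shared", "down"),
    "ehmt2-switch-up": ("develop-WT-only", "up"),
    "ehmt2-switch-down": ("develop-WT-only", "down"),
    "variance-inflated-only": ("none", "ns"),
    "null": ("none", "ns"),
}


def _default_fractions() -> dict[str, float]:
    return {
        "normal-both-up": 0.02,
        "normal-both-down": 0.02,
        "stage-switch-up": 0.02,
        "stage-switch-down": 0.02,
        "ehmt2-switch-up": 0.02,
        "ehmt2-switch-down": 0.02,
        "variance-inflated-only": 0.02,
    }


def _default_allele_fractions() -> dict[str, float]:
    return {
        "imprinted-MAT-silent": 0.01,
        "MAT-derepressed": 0.03,
        "both-derepressed-MAT-bias": 0.02,
    }


@dataclass
class SimConfig:
    """Study-condition parameters for one synthetic experiment.

    Expression scales are CPM-like relative abundances; ``effect_logfc`` is
    the planted effect in log2 units and ``inflation_factor`` multiplies the
    NB dispersion (squared biological CV) of the 6-somite mutant for the
    classes in ``inflated_classes`` ("all" inflates every gene).  Planted
    effect genes draw their baseline from a high-expression prior floored at
    ``planted_mu_min`` so that the planted classes constitute an
    adequate-power regime at the default replicate number.
    """

    n_genes: int = 5000
    n_repeat_loci: int = 400
    groups: tuple[str, ...] = DEFAULT_GROUPS
    replicates_per_group: int = 4
    lib_size_log_mean: float = float(np.log(1e6))
    lib_size_log_sd: float = 0.15
    baseline_mu_log_mean: float = float(np.log(30.0))
    baseline_mu_log_sd: float = 1.2
    planted_mu_log_mean: float = float(np.log(300.0))
    planted_mu_log_sd: float = 0.5
    planted_mu_min: float = 100.0
    dispersion_shape: float = 2.0
    dispersion_rate: float = 40.0
    effect_logfc: float = 2.0
    inflation_factor: float = 4.0
    inflated_classes: tuple[str, ...] | str = DEFAULT_INFLATED_CLASSES
    fractions: dict[str, float] = field(default_factory=_default_fractions)
    allele_fractions: dict[str, float] = field(default_factory=_default_allele_fractions)
    allelic_rate: float = 0.7
    imprinted_mat_fraction: float = 0.02
    derepression_fold: float = 8.0
    derepression_fold_minor: float = 3.0
    derepression_prob: float = 0.8
    # toy genome
    chrom_length: int = 10_000_000
    n_drivers: int = 8
    passengers_per_driver: int = 6
    gap_bp: int = 5_000
    n_independent_de_repeats: int = 30
    repeat_mu_log_mean: float = float(np.log(30.0))
    repeat_mu_log_sd: float = 0.5
    # methylation
    dmr_n_cpg: int = 15
    dmr_delta: float = 0.4
    n_tss_dmrs: int = 12
    background_beta: float = 0.75
    beta_noise_sd: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_repeat_loci <= 0:
            raise ValueError("n_genes and n_repeat_loci must be positive")
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2")
        bad = set(self.fractions) - set(GENE_CLASSES)
        if bad:
            raise ValueError(f"unknown gene classes in fractions: {sorted(bad)}")
        if any(f < 0 for f in self.fractions.values()) or sum(self.fractions.values()) > 1:
            raise ValueError("fractions must be non-negative and sum to <= 1")
        bad = set(self.allele_fractions) - set(ALLELE_TRUTH_CLASSES)
        if bad:
            raise ValueError(f"unknown allele classes: {sorted(bad)}")
        if sum(self.allele_fractions.values()) > 1:
            raise ValueError("allele fractions must sum to <= 1")
        if self.dmr_n_cpg < 12:
            raise ValueError("planted DMRs need at least 12 CpGs")
        if not 0 < self.allelic_rate <= 1:
            raise ValueError("allelic_rate must lie in (0, 1]")
        if self.inflated_classes != "all":
            bad = set(self.inflated_classes) - set(GENE_CLASSES)
            if bad:
                raise ValueError(f"unknown inflated classes: {sorted(bad)}")

    @property
    def sample_names(self) -> list[str]:
        return [f"{g}_{r + 1}" for g in self.groups for r in range(self.replicates_per_group)]


@dataclass
class TruthTable:
    """Planted ground truth: per-gene classes, repeat roles, DMR intervals."""

    genes: pd.DataFrame  # index gene; compartment_class, allele_class, base_cpm, phi
    repeats: pd.DataFrame  # index locus; role, cluster_id, strand, direction, subfamily, family
    dmrs: pd.DataFrame  # chrom, start, end, direction, n_cpg, kind, target

    def expected_compartment(self) -> pd.DataFrame:
        exp = self.genes["compartment_class"].map(EXPECTED_COMPARTMENT)
        return pd.DataFrame(
            {
                "label": exp.map(lambda t: t[0]),
                "direction": exp.map(lambda t: t[1]),
            },
            index=self.genes.index,
        )


@dataclass
class SimulatedStudy:
    """All input artifacts of one synthetic experiment."""

    sample_sheet: SampleSheet
    gene_counts: CountMatrix
    repeat_counts: CountMatrix
    maternal_counts: CountMatrix
    paternal_counts: CountMatrix
    gene_annotation: FeatureAnnotation
    exon_annotation: FeatureAnnotation
    repeat_annotation: FeatureAnnotation
    methylation: pd.DataFrame
    coverage: dict[str, tuple[pd.DataFrame, pd.DataFrame]]  # sample -> (+, -) tracks
    chrom_sizes: dict[str, int]
    wgbs_samples: dict[str, str]  # group label -> methylation column name

    @property
    def groups(self) -> pd.Series:
        return self.sample_sheet.groups


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _assign_classes(rng, n: int, fractions: dict[str, float], fallback: str) -> np.ndarray:
    classes = np.full(n, fallback, dtype=object)
    start = 0
    for cls, frac in fractions.items():
        k = int(round(frac * n))
        classes[start : start + k] = cls
        start += k
    perm = rng.permutation(n)
    return classes[perm]


def _nb_draw(rng, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + phi mu^2 (phi -> 0 is Poisson)."""
    phi = np.clip(phi, 1e-12, None)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
    return rng.poisson(lam)


def simulate_study(config: SimConfig) -> tuple[SimulatedStudy, TruthTable]:
    """Generate one synthetic study and its truth table (deterministic per seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    reps = config.replicates_per_group
    samples = config.sample_names
    n_samples = len(samples)
    group_of = np.repeat(np.array(config.groups, dtype=object), reps)

    # ----- sample sheet -----
    genotype = ["HOMO" if g.startswith("HOMO") else "WT" for g in group_of]
    stage = [12 if g.endswith("12") else 6 for g in group_of]
    cross = ["Jx1" if i % 2 == 0 else "1xJ" for i in range(n_samples)]
    sex = ["F" if rng.random() < 0.5 else "M" for _ in range(n_samples)]
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample": samples,
                "group": group_of,
                "genotype": genotype,
                "stage": stage,
                "cross": cross,
                "sex": sex,
            }
        )
    )

    # ----- gene classes, baselines, dispersions -----
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="feature")
    classes = _assign_classes(rng, n_genes, config.fractions, "null")
    base = np.exp(rng.normal(config.baseline_mu_log_mean, config.baseline_mu_log_sd, n_genes))
    planted = classes != "null"
    base[planted] = np.clip(
        np.exp(
            rng.normal(config.planted_mu_log_mean, config.planted_mu_log_sd, int(planted.sum()))
        ),
        config.planted_mu_min,
        None,
    )
    phi = np.clip(
        rng.gamma(config.dispersion_shape, 1.0 / config.dispersion_rate, n_genes), 1e-4, None
    )

    allele_classes = _assign_classes(rng, n_genes, config.allele_fractions, "biallelic")

    lib = np.exp(rng.normal(config.lib_size_log_mean, config.lib_size_log_sd, n_samples))

    # ----- group means (CPM scale), split into parental components -----
    eff = 2.0**config.effect_logfc
    is_wt_state = np.isin(group_of, ["WT6", "WT12", "MATWT6", "MATMUT6"])
    is_stage12 = np.isin(group_of, ["WT12", "HOMO12"])
    is_homo6 = group_of == "HOMO6"
    is_matmut = group_of == "MATMUT6"

    mult = np.ones((n_genes, n_samples))
    for cls, cond in (
        ("normal-both-up", is_wt_state),
        ("normal-both-down", ~is_wt_state),
        ("stage-switch-up", is_stage12),
        ("stage-switch-down", ~is_stage12),
        ("ehmt2-switch-up", is_stage12),
        ("ehmt2-switch-down", ~is_stage12),
    ):
        rows = classes == cls
        mult[np.ix_(rows, cond)] = eff

    # parental split: maternal fraction per gene
    f0 = np.where(
        np.isin(allele_classes, ["imprinted-MAT-silent", "MAT-derepressed"]),
        config.imprinted_mat_fraction,
        0.5,
    )
    mat_comp = base[:, None] * mult * f0[:, None]
    pat_comp = base[:, None] * mult * (1.0 - f0[:, None])

    # per-embryo random derepression of the maternal allele in the maternal-mutant arm
    derep_rows = np.isin(allele_classes, ["MAT-derepressed", "both-derepressed-MAT-bias"])
    derep_event = np.zeros((n_genes, n_samples), dtype=bool)
    if derep_rows.any() and is_matmut.any():
        event = rng.random((int(derep_rows.sum()), int(is_matmut.sum()))) < config.derepression_prob
        derep_event[np.ix_(derep_rows, is_matmut)] = event
        mat_comp[derep_event] *= config.derepression_fold
        minor = np.isin(allele_classes, ["both-derepressed-MAT-bias"])
        minor_event = derep_event & minor[:, None]
        pat_comp[minor_event] *= config.derepression_fold_minor

    mean_cpm = mat_comp + pat_comp
    with np.errstate(invalid="ignore"):
        mat_fraction = np.where(mean_cpm > 0, mat_comp / mean_cpm, 0.0)

    # ----- dispersion matrix with HOMO6 inflation -----
    phi_mat = np.repeat(phi[:, None], n_samples, axis=1)
    if config.inflated_classes == "all":
        inflated_rows = np.ones(n_genes, dtype=bool)
    else:
        inflated_rows = np.isin(classes, list(config.inflated_classes))
    phi_mat[np.ix_(inflated_rows, is_homo6)] *= config.inflation_factor

    # ----- counts -----
    mu_counts = mean_cpm / 1e6 * lib[None, :]
    gene_counts = _nb_draw(rng, mu_counts, phi_mat)
    assignable = rng.binomial(gene_counts, config.allelic_rate)
    maternal = rng.binomial(assignable, mat_fraction)
    paternal = assignable - maternal

    gene_cm = CountMatrix(pd.DataFrame(gene_counts, index=gene_ids, columns=samples))
    mat_cm = CountMatrix(
        pd.DataFrame(maternal, index=gene_ids, columns=samples), kind="allele_mat"
    )
    pat_cm = CountMatrix(
        pd.DataFrame(paternal, index=gene_ids, columns=samples), kind="allele_pat"
    )

    # ----- toy genome: genes on chr2 -----
    gene_spacing, gene_len = 10_000, 2_000
    gene_start = 5_000 + np.arange(n_genes) * gene_spacing
    gene_strand = np.where(np.arange(n_genes) % 2 == 0, "+", "-")
    gene_ann = FeatureAnnotation(
        pd.DataFrame(
            {
                "chrom": "chr2",
                "start": gene_start,
                "end": gene_start + gene_len,
                "name": gene_ids,
                "score": 0,
                "strand": gene_strand,
                "subfamily": "",
                "family": "",
            }
        )
    )
    exon_rows = []
    for s, name, strand in zip(gene_start, gene_ids, gene_strand):
        exon_rows.append((s, s + 500, name))
        exon_rows.append((s + 1500, s + gene_len, name))
    exon_ann = FeatureAnnotation(
        pd.DataFrame(
            {
                "chrom": "chr2",
                "start": [r[0] for r in exon_rows],
                "end": [r[1] for r in exon_rows],
                "name": [r[2] for r in exon_rows],
                "score": 0,
                "strand": np.repeat(gene_strand, 2),
                "subfamily": "",
                "family": "",
            }
        )
    )
    chr2_length = int(gene_start[-1] + gene_len + 5_000)

    # ----- repeats on chr1: driver clusters, independent DE, nulls -----
    repeat_rows, truth_repeat_rows, dmr_truth_rows = [], [], []
    passenger_subfams = [
        ("L1MdA", "L1", "LINE"),
        ("IAPEz-int", "ERVK", "LTR"),
        ("B1_Mus1", "Alu", "SINE"),
        ("MTA_Mm", "ERVL-MaLR", "LTR"),
        ("RLTR10", "ERV1", "LTR"),
        ("MERVL-int", "ERVL", "LTR"),
    ]
    other_subfams = [
        ("B2_Mm1a", "B2", "SINE"),
        ("L1MdF", "L1", "LINE"),
        ("RMER19B", "ERVK", "LTR"),
        ("MTB_Mm", "ERVL-MaLR", "LTR"),
        ("IAPLTR1", "ERVK", "LTR"),
        ("MIR", "MIR", "SINE"),
    ]
    driver_len, passenger_len = 1_000, 500
    cluster_pitch = 1_100_000
    n_cluster_loci = config.n_drivers * (1 + config.passengers_per_driver)
    transcripts = []  # (cluster_id, chrom, start, end, strand)
    locus_counter = 0

    def locus_name() -> str:
        nonlocal locus_counter
        name = f"rep{locus_counter:05d}"
        locus_counter += 1
        return name

    for k in range(config.n_drivers):
        strand = "+" if k % 2 == 0 else "-"
        anchor = 200_000 + k * cluster_pitch
        members = []
        if strand == "+":
            d_start = anchor
            members.append((d_start, d_start + driver_len, True))
            pos = d_start + driver_len
            for _ in range(config.passengers_per_driver):
                pos += config.gap_bp
                members.append((pos, pos + passenger_len, False))
                pos += passenger_len
            tx = (anchor, members[-1][1] + 8_000)
        else:
            pos = anchor
            for _ in range(config.passengers_per_driver):
                members.append((pos, pos + passenger_len, False))
                pos += passenger_len + config.gap_bp
            d_start = pos
            members.append((d_start, d_start + driver_len, True))
            tx = (anchor - 8_000, d_start + driver_len)
        for j, (s, e, is_driver) in enumerate(members):
            name = locus_name()
            if is_driver:
                subfam, fam, cls_ = "RLTR17", "ERVK", "LTR"
                role = "driver"
            else:
                subfam, fam, cls_ = passenger_subfams[j % len(passenger_subfams)]
                role = "passenger"
            repeat_rows.append(("chr1", s, e, name, 0, strand, subfam, fam))
            truth_repeat_rows.append((name, role, k, strand, "down", subfam, fam))
            if is_driver:
                dmr_truth_rows.append(("chr1", s, s + driver_len, "hyper", config.dmr_n_cpg, "te", name))
        transcripts.append((k, "chr1", tx[0], tx[1], strand))

    indep_anchor = 200_000 + config.n_drivers * cluster_pitch + 200_000
    for j in range(config.n_independent_de_repeats):
        s = indep_anchor + j * 30_000
        direction = "down" if j % 2 == 0 else "up"
        subfam, fam, cls_ = other_subfams[j % len(other_subfams)]
        name = locus_name()
        repeat_rows.append(("chr1", s, s + passenger_len, name, 0, "+" if j % 3 else "-", subfam, fam))
        truth_repeat_rows.append((name, "independent-DE", -1, repeat_rows[-1][5], direction, subfam, fam))

    n_null = config.n_repeat_loci - n_cluster_loci - config.n_independent_de_repeats
    null_anchor = indep_anchor + config.n_independent_de_repeats * 30_000 + 100_000
    for j in range(max(n_null, 0)):
        s = null_anchor + j * 1_500
        subfam, fam, cls_ = other_subfams[(j + 3) % len(other_subfams)]
        name = locus_name()
        repeat_rows.append(("chr1", s, s + 300, name, 0, "+" if j % 2 else "-", subfam, fam))
        truth_repeat_rows.append((name, "null", -1, repeat_rows[-1][5], "ns", subfam, fam))

    chr1_length = max(config.chrom_length, null_anchor + max(n_null, 0) * 1_500 + 10_000)
    repeat_ann = FeatureAnnotation(
        pd.DataFrame(
            repeat_rows,
            columns=["chrom", "start", "end", "name", "score", "strand", "subfamily", "family"],
        )
    )
    truth_repeats = pd.DataFrame(
        truth_repeat_rows,
        columns=["locus", "role", "cluster_id", "strand", "direction", "subfamily", "family"],
    ).set_index("locus")

    # repeat counts: derepressed-in-HOMO loci are higher in HOMO at both stages
    n_rep = len(truth_repeats)
    rep_base = np.exp(rng.normal(config.repeat_mu_log_mean, config.repeat_mu_log_sd, n_rep))
    rep_phi = np.clip(
        rng.gamma(config.dispersion_shape, 1.0 / config.dispersion_rate, n_rep), 1e-4, None
    )
    is_homo = np.isin(group_of, ["HOMO6", "HOMO12"])
    rep_mult = np.ones((n_rep, n_samples))
    direction = truth_repeats["direction"].to_numpy()
    rep_mult[np.ix_(direction == "down", is_homo)] = eff  # higher in HOMO = down in WT
    rep_mult[np.ix_(direction == "up", ~is_homo)] = eff
    rep_counts = _nb_draw(rng, rep_base[:, None] * rep_mult / 1e6 * lib[None, :], rep_phi[:, None])
    rep_cm = CountMatrix(
        pd.DataFrame(rep_counts, index=truth_repeats.index.rename("feature"), columns=samples),
        kind="repeat_locus",
    )

    # ----- methylation (one WT and one HOMO library) -----
    wgbs_samples = {"WT": "beta_WT", "HOMO": "beta_HOMO"}
    tss = gene_ann.tss()
    # choose promoter-DMR genes among planted genotype-effect genes
    down_genes = [g for g, c in zip(gene_ids, classes) if c == "normal-both-down"]
    up_genes = [g for g, c in zip(gene_ids, classes) if c == "normal-both-up"]
    n_half = config.n_tss_dmrs // 2
    hyper_genes = down_genes[:n_half]  # silenced in WT, promoter methylated in WT
    hypo_genes = up_genes[: config.n_tss_dmrs - n_half]
    dmr_gene_set = set(hyper_genes) | set(hypo_genes)

    meth_chrom, meth_pos, meth_wt, meth_homo = [], [], [], []

    def add_cpgs(chrom: str, positions: np.ndarray, wt_level: np.ndarray, homo_level: np.ndarray):
        noise_wt = rng.normal(0.0, config.beta_noise_sd, positions.size)
        noise_homo = rng.normal(0.0, config.beta_noise_sd, positions.size)
        meth_chrom.extend([chrom] * positions.size)
        meth_pos.extend(positions.tolist())
        meth_wt.extend(np.clip(wt_level + noise_wt, 0.0, 1.0).tolist())
        meth_homo.extend(np.clip(homo_level + noise_homo, 0.0, 1.0).tolist())

    dmr_halfwidth = (config.dmr_n_cpg - 1) * 60 // 2
    for g, t in zip(gene_ann.data["name"], tss.to_numpy()):
        t = int(t)
        if g in dmr_gene_set:
            inner = np.arange(t - dmr_halfwidth, t + dmr_halfwidth + 1, 60)
            outer = np.concatenate(
                [np.arange(t - 1400, t - dmr_halfwidth - 150, 200),
                 np.arange(t + dmr_halfwidth + 150, t + 1400, 200)]
            )
            wt_level = config.background_beta + (0.10 if g in hyper_genes else -0.30)
            homo_level = wt_level - config.dmr_delta if g in hyper_genes else wt_level + config.dmr_delta
            add_cpgs("chr2", inner, np.full(inner.size, wt_level), np.full(inner.size, homo_level))
            add_cpgs(
                "chr2",
                outer,
                np.full(outer.size, config.background_beta),
                np.full(outer.size, config.background_beta),
            )
            dmr_truth_rows.append(
                (
                    "chr2",
                    int(inner[0]),
                    int(inner[-1]) + 1,
                    "hyper" if g in hyper_genes else "hypo",
                    int(inner.size),
                    "tss",
                    g,
                )
            )
        else:
            positions = np.arange(t - 1400, t + 1400, 200)
            add_cpgs(
                "chr2",
                positions,
                np.full(positions.size, config.background_beta),
                np.full(positions.size, config.background_beta),
            )

    # driver-TE DMRs (hypomethylated in the mutant) plus null CpG blocks on chr1
    for chrom, s, e, direction_, n_cpg, kind, target in list(dmr_truth_rows):
        if kind != "te":
            continue
        positions = np.arange(s + 30, s + 30 + n_cpg * 60, 60)
        add_cpgs(
            chrom,
            positions,
            np.full(positions.size, 0.85),
            np.full(positions.size, 0.85 - config.dmr_delta),
        )
    null_blocks = 50
    for b in range(null_blocks):
        s = 9_000_000 + b * 8_000
        positions = np.arange(s, s + 15 * 200, 200)
        add_cpgs(
            "chr1",
            positions,
            np.full(positions.size, config.background_beta),
            np.full(positions.size, config.background_beta),
        )

    methylation = (
        pd.DataFrame(
            {
                "chrom": meth_chrom,
                "pos": meth_pos,
                wgbs_samples["WT"]: meth_wt,
                wgbs_samples["HOMO"]: meth_homo,
            }
        )
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )

    truth_dmrs = pd.DataFrame(
        dmr_truth_rows,
        columns=["chrom", "start", "end", "direction", "n_cpg", "kind", "target"],
    )

    # ----- stranded coverage: unidirectional read-through over clusters -----
    coverage: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    cluster_ivs = [(c, s, e, st) for c, _, s, e, st in transcripts]
    for j, sample in enumerate(samples):
        plus_rows, minus_rows = [], []
        if is_homo[j]:
            for _, s, e, st in [(c, s, e, st) for c, s, e, st in cluster_ivs]:
                value = float(np.round(rng.lognormal(np.log(8.0), 0.3), 3))
                (plus_rows if st == "+" else minus_rows).append(("chr1", s, e, value))
        # background noise on both strands, away from the planted clusters
        for _ in range(5):
            s = int(rng.integers(9_450_000, chr1_length - 3_000))
            w = int(rng.integers(500, 2_000))
            value = float(np.round(rng.uniform(0.5, 2.0), 3))
            (plus_rows if rng.random() < 0.5 else minus_rows).append(("chr1", s, s + w, value))
        cols = ["chrom", "start", "end", "value"]
        coverage[sample] = (
            pd.DataFrame(plus_rows, columns=cols).sort_values(["chrom", "start"]).reset_index(drop=True),
            pd.DataFrame(minus_rows, columns=cols).sort_values(["chrom", "start"]).reset_index(drop=True),
        )

    truth_genes = pd.DataFrame(
        {
            "compartment_class": classes,
            "allele_class": allele_classes,
            "base_cpm": base,
            "phi": phi,
        },
        index=gene_ids.rename("gene"),
    )

    study = SimulatedStudy(
        sample_sheet=sheet,
        gene_counts=gene_cm,
        repeat_counts=rep_cm,
        maternal_counts=mat_cm,
        paternal_counts=pat_cm,
        gene_annotation=gene_ann,
        exon_annotation=exon_ann,
        repeat_annotation=repeat_ann,
        methylation=methylation,
        coverage=coverage,
        chrom_sizes={"chr1": int(chr1_length), "chr2": chr2_length},
        wgbs_samples=wgbs_samples,
    )
    truth = TruthTable(genes=truth_genes, repeats=truth_repeats, dmrs=truth_dmrs)
    return study, truth


# ---------------------------------------------------------------------------
# round-trip I/O
# ---------------------------------------------------------------------------


def write_study(study: SimulatedStudy, truth: TruthTable, directory) -> None:
    """Write every study artifact in its plain-text exchange format."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_sample_sheet(study.sample_sheet, d / "samples.tsv")
    write_counts(study.gene_counts, d / "counts.tsv")
    write_counts(study.repeat_counts, d / "repeats_counts.tsv")
    write_counts(study.maternal_counts, d / "counts_mat.tsv")
    write_counts(study.paternal_counts, d / "counts_pat.tsv")
    write_bed(study.gene_annotation, d / "genes.bed")
    write_bed(study.exon_annotation, d / "exons.bed")
    write_bed(study.repeat_annotation, d / "repeats.bed")
    write_methylation(study.methylation, d / "methylation.tsv")
    for sample, (plus, minus) in study.coverage.items():
        write_bedgraph(plus, d / f"coverage_{sample}_plus.bedgraph")
        write_bedgraph(minus, d / f"coverage_{sample}_minus.bedgraph")
    pd.Series(study.chrom_sizes).rename("length").rename_axis("chrom").reset_index().to_csv(
        d / "chrom_sizes.tsv", sep="\t", index=False
    )
    pd.Series(study.wgbs_samples).rename("column").rename_axis("group").reset_index().to_csv(
        d / "wgbs_samples.tsv", sep="\t", index=False
    )
    truth.genes.to_csv(d / "truth.tsv", sep="\t")
    truth.repeats.to_csv(d / "truth_repeats.tsv", sep="\t")
    truth.dmrs.to_csv(d / "truth_dmrs.tsv", sep="\t", index=False)


def read_study(directory) -> tuple[SimulatedStudy, TruthTable | None]:
    """Read a study directory written by :func:`write_study` (truth optional)."""
    d = Path(directory)
    sheet = read_sample_sheet(d / "samples.tsv")
    coverage = {}
    for sample in sheet.samples:
        plus_path = d / f"coverage_{sample}_plus.bedgraph"
        minus_path = d / f"coverage_{sample}_minus.bedgraph"
        if plus_path.exists() and minus_path.exists():
            coverage[sample] = (read_bedgraph(plus_path), read_bedgraph(minus_path))
    chrom_sizes = {}
    if (d / "chrom_sizes.tsv").exists():
        cs = pd.read_csv(d / "chrom_sizes.tsv", sep="\t")
        chrom_sizes = dict(zip(cs["chrom"], cs["length"].astype(int)))
    wgbs = {}
    if (d / "wgbs_samples.tsv").exists():
        ws = pd.read_csv(d / "wgbs_samples.tsv", sep="\t")
        wgbs = dict(zip(ws["group"], ws["column"]))
    methylation = (
        read_methylation(d / "methylation.tsv")
        if (d / "methylation.tsv").exists()
        else pd.DataFrame(columns=["chrom", "pos"])
    )
    study = SimulatedStudy(
        sample_sheet=sheet,
        gene_counts=read_counts(d / "counts.tsv"),
        repeat_counts=read_counts(d / "repeats_counts.tsv", kind="repeat_locus"),
        maternal_counts=read_counts(d / "counts_mat.tsv", kind="allele_mat"),
        paternal_counts=read_counts(d / "counts_pat.tsv", kind="allele_pat"),
        gene_annotation=read_bed(d / "genes.bed"),
        exon_annotation=read_bed(d / "exons.bed"),
        repeat_annotation=read_bed(d / "repeats.bed"),
        methylation=methylation,
        coverage=coverage,
        chrom_sizes=chrom_sizes,
        wgbs_samples=wgbs,
    )
    truth = None
    if (d / "truth.tsv").exists():
        # keep_default_na: the planted class literally named "null" is data
        na = {"keep_default_na": False, "na_values": [""]}
        truth = TruthTable(
            genes=pd.read_csv(d / "truth.tsv", sep="\t", index_col=0, **na),
            repeats=pd.read_csv(d / "truth_repeats.tsv", sep="\t", index_col=0, **na),
            dmrs=pd.read_csv(d / "truth_dmrs.tsv", sep="\t", **na),
        )
    return study, truth
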