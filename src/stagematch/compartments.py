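"""Contrast decomposition: "what it takes to be normal" vs "what it takes to develop".

A developmentally delayed homozygous mutant (HOMO) reaches the 6-somite stage
when its wild-type (WT) uterus mates are at 12 somites, so the conventional
uterus-mate comparison (WT12 vs HOMO6) confounds genotype with developmental
progress.  Stage-matched contrasts disentangle the two:

====  =================  ===========================================
name  contrast (A vs B)  meaning of an ``up`` call (higher in A)
====  =================  ===========================================
N6    WT6  vs HOMO6      needs the gene high to *be normal* at 6 somites
N12   WT12 vs HOMO12     same at 12 somites
D_WT  WT12 vs WT6        rises while *developing* from 6 to 12 somites (WT)
D_HOMO HOMO12 vs HOMO6   same within the mutant
CONV  WT12 vs HOMO6      the confounded conventional comparison
====  =================  ===========================================

``three_way_decompose`` dissects CONV against N6 and D_WT: a CONV hit that is
also a stage effect in wild type alone is a developmental false positive of
the conventional design, while a stage-matched genotype hit absent from CONV
would have been missed by it.  ``four_way_classify`` places each feature into
the Venn compartments of {N6, N12, D_WT, D_HOMO} per direction; genes
significant only in D_WT (``develop-WT-only``) are developmental switches
that require the mutated gene to be executed precisely.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .de import ContrastResults

__all__ = [
    "CONTRAST_NAMES",
    "FOURWAY_CONTRASTS",
    "CompartmentAssignment",
    "membership_table",
    "three_way_decompose",
    "four_way_classify",
    "compartment_tables",
]

CONTRAST_NAMES = ["N6", "N12", "D_WT", "D_HOMO", "CONV"]
FOURWAY_CONTRASTS = ["N6", "N12", "D_WT", "D_HOMO"]
THREEWAY_CONTRASTS = ["CONV", "N6", "D_WT"]

_NORMAL = ("N6", "N12")
_DEVELOP = ("D_WT", "D_HOMO")

FOURWAY_LABELS = [
    "normal-both-stages",
    "normal-6-only",
    "normal-12-only",
    "develop-shared",
    "develop-WT-only",
    "develop-HOMO-only",
    "mixed",
    "none",
]

THREEWAY_LABELS = [
    "genotype-effect",
    "developmental-false-positive",
    "both",
    "conventional-only",
    "missed-by-conventional",
    "none",
]


def membership_table(results: dict[str, ContrastResults]) -> pd.DataFrame:
    """Combine per-contrast DE calls into one feature x contrast call table.

    All contrasts must be computed with identical thresholds on one shared
    filtered feature universe, so that Venn arithmetic over the calls is well
    defined; features absent from a contrast's table get ``ns``.
    """
    universe = pd.Index([])
    for res in results.values():
        universe = universe.union(res.table.index)
    table = pd.DataFrame("ns", index=universe, columns=list(results))
    for name, res in results.items():
        table.loc[res.table.index, name] = res.table["call"].to_numpy()
    return table


def _classify_fourway_calls(n6: str, n12: str, d_wt: str, d_homo: str) -> tuple[str, str]:
    """Pure rule table mapping four calls to (label, direction)."""
    calls = {"N6": n6, "N12": n12, "D_WT": d_wt, "D_HOMO": d_homo}
    directions = {c for c in calls.values() if c != "ns"}
    if not directions:
        return "none", "ns"
    if len(directions) > 1:
        # opposite directions in two contrasts: not forced into a Venn cell
        order = [calls[c] for c in FOURWAY_CONTRASTS if calls[c] != "ns"]
        return "mixed", order[0]
    direction = directions.pop()
    normal_hit = any(calls[c] == direction for c in _NORMAL)
    develop_hit = any(calls[c] == direction for c in _DEVELOP)
    if normal_hit and develop_hit:
        return "mixed", direction
    if normal_hit:
        if calls["N6"] == direction and calls["N12"] == direction:
            return "normal-both-stages", direction
        if calls["N6"] == direction:
            return "normal-6-only", direction
        return "normal-12-only", direction
    if calls["D_WT"] == direction and calls["D_HOMO"] == direction:
        return "develop-shared", direction
    if calls["D_WT"] == direction:
        return "develop-WT-only", direction
    return "develop-HOMO-only", direction


@dataclass
class CompartmentAssignment:
    """Per-feature compartment label and direction, plus the call table used."""

    assignment: pd.DataFrame  # columns: label, direction
    memberships: pd.DataFrame

    def features_in(self, label: str, direction: str | None = None) -> pd.Index:
        mask = self.assignment["label"] == label
        if direction is not None:
            mask &= self.assignment["direction"] == direction
        return self.assignment.index[mask]

    def counts(self) -> pd.DataFrame:
        return (
            self.assignment.groupby(["label", "direction"], observed=True)
            .size()
            .rename("n_features")
            .reset_index()
        )


def four_way_classify(memberships: pd.DataFrame) -> CompartmentAssignment:
    """Assign each feature to a Venn compartment of the four stage-matched contrasts.

    The label is a pure function of the four calls.  Features hit in both a
    "normal" (N6/N12) and a "develop" (D_WT/D_HOMO) contrast, or with
    opposite directions in two contrasts, are labelled ``mixed``.
    """
    missing = [c for c in FOURWAY_CONTRASTS if c not in memberships.columns]
    if missing:
        raise ValueError(f"membership table lacks contrast(s): {missing}")
    cache: dict[tuple[str, ...], tuple[str, str]] = {}
    labels, directions = [], []
    for row in memberships[FOURWAY_CONTRASTS].itertuples(index=False):
        key = tuple(row)
        if key not in cache:
            cache[key] = _classify_fourway_calls(*key)
        lab, direc = cache[key]
        labels.append(lab)
        directions.append(direc)
    assignment = pd.DataFrame(
        {"label": labels, "direction": directions}, index=memberships.index
    )
    return CompartmentAssignment(assignment=assignment, memberships=memberships)


def three_way_decompose(memberships: pd.DataFrame) -> pd.DataFrame:
    """Dissect the conventional uterus-mate comparison per direction.

    For each direction separately (a feature can in principle appear in both):

    * CONV and N6 agree, D_WT silent: a true genotype effect — "what it takes
      to be normal".
    * CONV and D_WT agree, N6 silent: the hit is a normal developmental
      change, i.e. a false positive of the conventional comparison.
    * all three: both effects overlap.
    * CONV alone: only the confounded design sees it.
    * N6 without CONV: a genotype effect the conventional comparison misses.

    Returns a long frame (feature, direction, label) with one row per
    (feature, direction) where at least one contrast is called; features
    called nowhere get a single ``none`` row.
    """
    missing = [c for c in THREEWAY_CONTRASTS if c not in memberships.columns]
    if missing:
        raise ValueError(f"membership table lacks contrast(s): {missing}")
    rows = []
    for feature, row in memberships[THREEWAY_CONTRASTS].iterrows():
        any_hit = False
        for direction in ("up", "down"):
            conv = row["CONV"] == direction
            n6 = row["N6"] == direction
            d_wt = row["D_WT"] == direction
            if conv and n6 and d_wt:
                label = "both"
            elif conv and n6:
                label = "genotype-effect"
            elif conv and d_wt:
                label = "developmental-false-positive"
            elif conv:
                label = "conventional-only"
            elif n6:
                label = "missed-by-conventional"
            else:
                continue
            rows.append((feature, direction, label))
            any_hit = True
        if not any_hit:
            rows.append((feature, "ns", "none"))
    return pd.DataFrame(rows, columns=["feature", "direction", "label"]).set_index("feature")


def compartment_tables(
    assignment: CompartmentAssignment,
    log2cpm: pd.DataFrame,
    directory: str | Path | None = None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-compartment log2-CPM matrices over all study samples.

    One table per (label, direction) pair including the ``none``/``mixed``
    cells, so the tables partition the classified feature universe.  When
    ``directory`` is given each table is written as a TSV suitable for
    heatmap rendering.
    """
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for (label, direction), sub in assignment.assignment.groupby(
        ["label", "direction"], observed=True
    ):
        feats = sub.index
        feats = feats[feats.isin(log2cpm.index)]
        tables[(label, direction)] = log2cpm.loc[feats]
    if directory is not None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for (label, direction), tab in tables.items():
            safe = label.replace("/", "-")
            out = tab.copy()
            out.index.name = "feature"
            out.to_csv(directory / f"compartment_{safe}_{direction}.tsv", sep="\t")
    return tables
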