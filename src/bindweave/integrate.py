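"""Classification logic integrating the omics layers.

This module holds the decision rules of the analysis: differential-feature
classes under FDR + fold-change thresholds, DNA-binding dependence from a
wild-type vs binding-dead (C88A) contrast, direct transcription-factor
targets (binding-dependent dysregulation with a binding site within a
proximity window), accessibility classes over shared and genotype-specific
peaks, binding/accessibility overlap reporting, co-occupancy clusters and
their motif spacing, dependence on a second factor from
overexpression/knockout contrasts, proximity-labeling interactome calls,
and the CRISPR indel-frequency fold-change summary.

Fold-change thresholds are stated on the linear scale (``FC >= 2`` means
``|log2FC| >= 1``); all threshold comparisons are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GeneAnnotation,
    PeakSet,
    count_overlapping,
    genes_within,
    intersect_consensus,
)
from .motifscan import MotifHit, SpacingSummary, heterotypic_spacing
from .permstats import ContingencyTable2x2, differential_count_test, fisher_exact


@dataclass
class Thresholds:
    """Classification thresholds (fold-changes on the linear scale)."""

    deg_fdr: float = 0.05
    deg_fc: float = 2.0
    atac_fdr: float = 0.05
    atac_fc: float = 1.5
    interactome_fdr: float = 0.05
    interactome_fc: float = 2.0
    proximity: int = 1000  # bases

    def __post_init__(self) -> None:
        for name in ("deg_fdr", "atac_fdr", "interactome_fdr"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("deg_fc", "atac_fc", "interactome_fc"):
            if getattr(self, name) <= 1:
                raise ValueError(f"{name} must be > 1")
        if self.proximity <= 0:
            raise ValueError("proximity must be positive")


def classify_deg(
    diff: pd.DataFrame, thresholds: Thresholds, fdr: Optional[float] = None, fc: Optional[float] = None
) -> pd.DataFrame:
    """Label each feature ``up`` / ``down`` / ``ns``.

    ``diff`` must carry ``log2fc`` and ``q`` columns (q precomputed).
    ``up`` requires ``q <= fdr`` and ``log2fc >= log2(fc)``; ``down`` is
    symmetric; everything else is ``ns``. The returned frame adds a
    ``deg_class`` column; the three labels partition the features.
    """
    if "q" not in diff.columns:
        raise ValueError("differential table must carry a precomputed 'q' column")
    if "log2fc" not in diff.columns:
        raise ValueError("differential table must carry a 'log2fc' column")
    fdr = thresholds.deg_fdr if fdr is None else fdr
    fc = thresholds.deg_fc if fc is None else fc
    lfc_cut = np.log2(fc)
    out = diff.copy()
    sig = out["q"] <= fdr
    out["deg_class"] = "ns"
    out.loc[sig & (out["log2fc"] >= lfc_cut), "deg_class"] = "up"
    out.loc[sig & (out["log2fc"] <= -lfc_cut), "deg_class"] = "down"
    return out


def binding_dependence(
    deg_wt_vs_empty: pd.DataFrame,
    deg_wt_vs_c88a: pd.DataFrame,
    thresholds: Thresholds,
    require_same_direction: bool = True,
) -> pd.Series:
    """Flag genes whose dysregulation depends on DNA binding.

    A gene is binding-dependent iff it is a DEG in the WT-vs-empty contrast
    AND a DEG in the WT-vs-C88A contrast — by default in the same direction
    (``require_same_direction=False`` gives the direction-agnostic
    reading). Both inputs must be classified frames over the same gene
    universe (error lists the symmetric difference otherwise).
    """
    u1, u2 = set(deg_wt_vs_empty.index), set(deg_wt_vs_c88a.index)
    if u1 != u2:
        raise ValueError(f"gene universes differ; symmetric difference: {sorted(u1 ^ u2)[:10]}")
    a = deg_wt_vs_empty["deg_class"].reindex(deg_wt_vs_empty.index)
    b = deg_wt_vs_c88a["deg_class"].reindex(deg_wt_vs_empty.index)
    deg_a = a.isin(["up", "down"])
    deg_b = b.isin(["up", "down"])
    if require_same_direction:
        return deg_a & deg_b & (a == b)
    return deg_a & deg_b


def call_direct_targets(
    deg_calls: pd.DataFrame,
    binding_dependent: pd.Series,
    sites: PeakSet,
    ann: GeneAnnotation,
    thresholds: Thresholds,
) -> pd.DataFrame:
    """Direct targets: binding-dependent DEGs with a site within the
    proximity window of the gene body.

    Returns a frame indexed by gene with ``deg_class``,
    ``binding_dependent``, ``distance_to_nearest_site`` (NaN when farther
    than the window or no site), and ``direct_target``. The invariant
    ``direct_target => binding_dependent and distance <= proximity`` holds
    by construction.
    """
    near = genes_within(sites, ann, max_distance=thresholds.proximity) if len(sites) else {}
    out = deg_calls.copy()
    out["binding_dependent"] = binding_dependent.reindex(out.index).fillna(False).astype(bool)
    out["distance_to_nearest_site"] = [near.get(g, np.nan) for g in out.index]
    out["direct_target"] = (
        out["binding_dependent"]
        & out["deg_class"].isin(["up", "down"])
        & out["distance_to_nearest_site"].notna()
    )
    return out


def proximity_expression_association(target_calls: pd.DataFrame) -> dict[str, dict]:
    """Association between site proximity and expression direction.

    For each direction (``up``, ``down``), builds the 2×2 table
    (within-window vs beyond) × (direction vs ``ns``) and applies Fisher's
    exact test. Genes must all carry a proximity status (the
    ``distance_to_nearest_site`` column; NaN = beyond the window).
    Degenerate margins are flagged and given p = 1.
    """
    proximal = target_calls["distance_to_nearest_site"].notna()
    results: dict[str, dict] = {}
    for direction in ("up", "down"):
        is_dir = target_calls["deg_class"] == direction
        is_ns = target_calls["deg_class"] == "ns"
        a = int((proximal & is_dir).sum())
        b = int((proximal & is_ns).sum())
        c = int((~proximal & is_dir).sum())
        d = int((~proximal & is_ns).sum())
        degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
        odds, p = fisher_exact(ContingencyTable2x2(a, b, c, d))
        results[direction] = {
            "table": (a, b, c, d),
            "odds_ratio": odds,
            "p": 1.0 if degenerate else p,
            "degenerate": degenerate,
        }
    return results


def accessibility_classes(
    shared_diff: pd.DataFrame,
    a_only: pd.DataFrame,
    b_only: pd.DataFrame,
    thresholds: Thresholds,
) -> dict[str, list]:
    """Five-way accessibility labeling.

    ``shared_diff`` (regions present in both genotypes) must carry
    ``log2fc`` and ``q``; shared regions are labeled increased / decreased
    / unchanged by the FDR + fold-change rule. ``a_only`` / ``b_only``
    (regions present in exactly one genotype's peak list, indexed by region
    id with a ``log2fc`` column on normalized counts) become genotype-
    specific when they pass the fold-change cut alone — the criterion for
    these is deliberately asymmetric, with no FDR requirement. A region id
    appearing in both "only" frames violates the partition and is an error.
    """
    overlap_ids = set(a_only.index) & set(b_only.index)
    if overlap_ids:
        raise ValueError(f"regions present in both genotype-specific lists: {sorted(overlap_ids)[:5]}")
    lfc_cut = np.log2(thresholds.atac_fc)
    sig = shared_diff["q"] <= thresholds.atac_fdr
    increased = shared_diff.index[sig & (shared_diff["log2fc"] >= lfc_cut)].tolist()
    decreased = shared_diff.index[sig & (shared_diff["log2fc"] <= -lfc_cut)].tolist()
    unchanged = shared_diff.index.difference(increased + decreased).tolist()
    a_specific = a_only.index[a_only["log2fc"].abs() >= lfc_cut].tolist()
    b_specific = b_only.index[b_only["log2fc"].abs() >= lfc_cut].tolist()
    return {
        "increased": increased,
        "decreased": decreased,
        "unchanged": unchanged,
        "a_specific": a_specific,
        "b_specific": b_specific,
    }


def binding_accessibility_report(
    sites: PeakSet,
    accessible: PeakSet,
    increased: Optional[PeakSet] = None,
    decreased: Optional[PeakSet] = None,
) -> dict[str, float]:
    """Overlap of binding sites with accessible / differential regions.

    Reports the fraction of binding sites overlapping (>= 1 bp) the
    accessible region set, and optionally the increased/decreased
    accessibility classes, with raw counts.
    """
    n = len(sites)
    out: dict[str, float] = {"n_sites": n}
    k, _ = count_overlapping(sites, accessible)
    out["n_overlap_accessible"] = k
    out["fraction_accessible"] = k / n if n else float("nan")
    for name, ps in (("increased", increased), ("decreased", decreased)):
        if ps is not None:
            k, _ = count_overlapping(sites, ps)
            out[f"n_overlap_{name}"] = k
            out[f"fraction_{name}"] = k / n if n else float("nan")
    if increased is not None and decreased is not None:
        out["n_changed"] = out["n_overlap_increased"] + out["n_overlap_decreased"]
        out["fraction_changed"] = out["n_changed"] / n if n else float("nan")
    return out


def cooccupancy(
    sites_a: PeakSet,
    sites_b: PeakSet,
    hits_a: Optional[Sequence[MotifHit]] = None,
    hits_b: Optional[Sequence[MotifHit]] = None,
) -> tuple[PeakSet, Optional[SpacingSummary]]:
    """Co-bound clusters (>= 1 bp overlap between the two site sets) and,
    when motif hit lists are supplied, the heterotypic spacing of hits
    restricted to cluster territory."""
    clusters = intersect_consensus(sites_a, sites_b)
    summary = None
    if hits_a is not None and hits_b is not None and len(clusters):
        summary = heterotypic_spacing(hits_a, hits_b, restrict_to=clusters)
    return clusters, summary


def gata2_dependency(
    deg_primary: pd.DataFrame,
    deg_factor_oe: pd.DataFrame,
    deg_factor_ko: pd.DataFrame,
) -> dict[str, list[str]]:
    """Coordinate and dependent gene sets for a candidate mediator factor.

    All three frames must be classified (``deg_class``) over the same gene
    universe. A primary-contrast DEG is *coordinate* when the factor's
    overexpression moves it in the same direction, and *dependent* when the
    factor's knockout moves it in the opposite direction (up in the primary
    contrast and down upon knockout, or the mirror). Direction splits are
    reported.
    """
    u = set(deg_primary.index)
    for other in (deg_factor_oe, deg_factor_ko):
        if set(other.index) != u:
            raise ValueError(
                f"gene universes differ; symmetric difference: {sorted(u ^ set(other.index))[:10]}"
            )
    p = deg_primary["deg_class"]
    oe = deg_factor_oe["deg_class"].reindex(deg_primary.index)
    ko = deg_factor_ko["deg_class"].reindex(deg_primary.index)
    coord_up = p.index[(p == "up") & (oe == "up")].tolist()
    coord_down = p.index[(p == "down") & (oe == "down")].tolist()
    dep_up = p.index[(p == "up") & (ko == "down")].tolist()
    dep_down = p.index[(p == "down") & (ko == "up")].tolist()
    return {
        "coordinate": coord_up + coord_down,
        "coordinate_up": coord_up,
        "coordinate_down": coord_down,
        "dependent": dep_up + dep_down,
        "dependent_up": dep_up,
        "dependent_down": dep_down,
    }


def interactome_classify(
    counts: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    thresholds: Thresholds,
) -> pd.DataFrame:
    """Proximity-labeling interactome calls from spectral counts.

    ``groups`` must provide sample lists for ``control``, ``WT_N``,
    ``WT_C`` and ``C88A`` (>= 2 replicates each). A protein is
    ``enriched_vs_control`` when the pooled wild-type orientations
    (WT_N ∪ WT_C) pass FDR + fold-change *upward* against the control
    construct, and additionally ``binding_dependent`` when the pooled
    wild-type groups pass the same thresholds upward against the
    binding-dead construct. Per-orientation contrasts are also emitted
    (``log2fc_n_vs_control``, ``log2fc_c_vs_control``). Normalized (CPM)
    group means per construct are included for reporting.
    """
    required = {"control", "WT_N", "WT_C", "C88A"}
    missing = required - set(groups)
    if missing:
        raise ValueError(f"missing construct groups: {sorted(missing)}")
    for g in required:
        if len(groups[g]) < 2:
            raise ValueError(f"construct {g} needs >= 2 replicates")
    wt = list(groups["WT_N"]) + list(groups["WT_C"])
    lfc_cut = np.log2(thresholds.interactome_fc)

    vs_control = differential_count_test(counts, wt, list(groups["control"]))
    vs_c88a = differential_count_test(counts, wt, list(groups["C88A"]))
    enriched = (vs_control["q"] <= thresholds.interactome_fdr) & (
        vs_control["log2fc"] >= lfc_cut
    )
    dependent = enriched & (vs_c88a["q"] <= thresholds.interactome_fdr) & (
        vs_c88a["log2fc"] >= lfc_cut
    )

    out = pd.DataFrame(index=counts.index)
    out["log2fc_vs_control"] = vs_control["log2fc"]
    out["q_vs_control"] = vs_control["q"]
    out["log2fc_vs_c88a"] = vs_c88a["log2fc"]
    out["q_vs_c88a"] = vs_c88a["q"]
    out["enriched_vs_control"] = enriched
    out["binding_dependent"] = dependent
    for orient in ("WT_N", "WT_C"):
        sub = differential_count_test(counts, list(groups[orient]), list(groups["control"]))
        out[f"log2fc_{orient.lower()}_vs_control"] = sub["log2fc"]
    lib = counts.sum(axis=0)
    cpm = counts / lib * 1e6
    for g in ("control", "WT_N", "WT_C", "C88A"):
        out[f"cpm_{g}"] = cpm[list(groups[g])].mean(axis=1)
    return out


def indel_fold_change(
    initial: Sequence[float], final: Sequence[float]
) -> tuple[float, float, float]:
    """Fold-change of mean indel frequency between two timepoints.

    ``initial`` and ``final`` are per-replicate allele frequencies in
    percent. Returns ``(mean_initial, mean_final, fold_change)`` with the
    fold-change rounded to two decimals (round-half-even);
    ``fold_change = inf`` when the final mean is 0 (flagged via the value
    itself).
    """
    initial = list(initial)
    final = list(final)
    if not initial or not final:
        raise ValueError("frequency lists must be non-empty")
    for v in list(initial) + list(final):
        if not 0 <= v <= 100:
            raise ValueError("frequencies must be percentages in [0, 100]")
    mean_i = float(np.mean(initial))
    mean_f = float(np.mean(final))
    if mean_f == 0:
        return mean_i, mean_f, float("inf")
    return mean_i, mean_f, round(mean_i / mean_f, 2)
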