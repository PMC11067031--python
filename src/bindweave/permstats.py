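"""Permutation nulls, exact tests, and multiple-testing control.

Two permutation schemes underpin the genomic enrichment claims:

* **Region enrichment** — how many query regions overlap a reference set,
  against a null that relocates each query interval (length preserved)
  uniformly and independently within a universe (whole genome by default,
  or a supplied region set such as accessible chromatin).
* **Spacing** — mean nearest-neighbor distance between two motif hit
  classes, against a null that repositions the second class uniformly
  (per-chromosome counts preserved); one-sided for "closer than chance".

Empirical p-values use the plus-one Monte-Carlo estimator
``(1 + #{null at least as extreme}) / (1 + n_perm)`` and are never 0.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, PeakSet, count_overlapping, overlap_flags_sorted
from .motifscan import MotifHit, heterotypic_spacing


@dataclass
class PermutationResult:
    """Observed statistic, its Monte-Carlo null, and the empirical p."""

    observed_statistic: float
    null_samples: np.ndarray
    empirical_p: float
    n_perm: int
    seed: int
    alternative: str  # "greater" (enrichment) or "less" (closer than chance)

    def to_json(self, path: Optional[str | Path] = None) -> str:
        payload = json.dumps(
            {
                "observed_statistic": self.observed_statistic,
                "empirical_p": self.empirical_p,
                "n_perm": self.n_perm,
                "seed": self.seed,
                "alternative": self.alternative,
                "null_mean": float(np.mean(self.null_samples)),
                "null_samples": np.asarray(self.null_samples).tolist(),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _empirical_p(observed: float, null: np.ndarray, alternative: str) -> float:
    if alternative == "greater":
        extreme = int(np.sum(null >= observed))
    elif alternative == "less":
        extreme = int(np.sum(null <= observed))
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return (1 + extreme) / (1 + null.size)


Universe = Union[Mapping[str, int], PeakSet]


def _placement_segments(universe: Universe) -> list[tuple[str, int, int]]:
    """Universe → list of (chrom, segment_start, segment_end) slots."""
    if isinstance(universe, PeakSet):
        return [(iv.chrom, iv.start, iv.end) for iv in universe.merge()]
    return [(chrom, 0, int(size)) for chrom, size in universe.items()]


def region_enrichment_perm(
    query: PeakSet,
    reference: PeakSet,
    universe: Universe,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationResult:
    """One-sided permutation test for overlap enrichment of query in reference.

    The observed statistic is the number of query intervals with a >= 1 bp
    reference overlap. Each permutation relocates every query interval,
    length preserved, uniformly over all placements that fit entirely inside
    the universe (whole chromosomes when ``universe`` is a chrom-sizes
    mapping; merged regions when it is a :class:`PeakSet`).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if len(query) == 0:
        raise ValueError("empty query set")
    segments = _placement_segments(universe)
    seg_chrom = [s[0] for s in segments]
    seg_start = np.array([s[1] for s in segments], dtype=np.int64)
    seg_end = np.array([s[2] for s in segments], dtype=np.int64)
    seg_len = seg_end - seg_start

    observed, _ = count_overlapping(query, reference)
    rng = np.random.default_rng(seed)

    ref_sorted = {
        c: (np.sort(s), np.sort(e)) for c, (s, e) in reference.by_chrom().items()
    }
    chrom_ids = {c: k for k, c in enumerate(sorted(set(seg_chrom)))}
    seg_chrom_id = np.array([chrom_ids[c] for c in seg_chrom])

    # per query interval: sample a segment (weight = #valid placements) and an
    # offset, for all permutations at once
    placements_chrom = np.empty((n_perm, len(query)), dtype=np.int32)
    placements_start = np.empty((n_perm, len(query)), dtype=np.int64)
    for i, iv in enumerate(query):
        length = len(iv)
        slots = seg_len - length + 1
        valid = slots > 0
        if not valid.any():
            raise ValueError(
                f"universe has no segment large enough for a {length} bp interval"
            )
        weights = np.where(valid, slots, 0).astype(float)
        weights /= weights.sum()
        seg_idx = rng.choice(len(segments), size=n_perm, p=weights)
        offsets = rng.integers(0, slots[seg_idx])
        placements_chrom[:, i] = seg_chrom_id[seg_idx]
        placements_start[:, i] = seg_start[seg_idx] + offsets
    lengths = np.array([len(iv) for iv in query], dtype=np.int64)
    placements_end = placements_start + lengths[None, :]

    null = np.zeros(n_perm, dtype=np.int64)
    perm_idx = np.repeat(np.arange(n_perm), len(query))
    flat_chrom = placements_chrom.ravel()
    flat_start = placements_start.ravel()
    flat_end = placements_end.ravel()
    for chrom, cid in chrom_ids.items():
        mask = flat_chrom == cid
        if not mask.any() or chrom not in ref_sorted:
            continue
        r_starts, r_ends = ref_sorted[chrom]
        flags = overlap_flags_sorted(flat_start[mask], flat_end[mask], r_starts, r_ends)
        np.add.at(null, perm_idx[mask][flags], 1)

    return PermutationResult(
        observed_statistic=float(observed),
        null_samples=null.astype(float),
        empirical_p=_empirical_p(observed, null, "greater"),
        n_perm=n_perm,
        seed=seed,
        alternative="greater",
    )


def spacing_perm(
    hits_a: Sequence[MotifHit],
    hits_b: Sequence[MotifHit],
    universe: Universe,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationResult:
    """One-sided permutation test for motif pairs being closer than chance.

    Observed statistic: mean nearest-neighbor start-to-start distance from
    a-hits to b-hits (same chromosome). Null: b-hit positions are redrawn
    uniformly within the universe, preserving the per-chromosome hit count;
    the p-value is one-sided for the observed mean being *smaller* than the
    null means.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    summary = heterotypic_spacing(hits_a, hits_b)
    observed = summary.mean_spacing
    rng = np.random.default_rng(seed)

    segments = _placement_segments(universe)
    a_by_chrom: dict[str, np.ndarray] = {}
    for h in hits_a:
        a_by_chrom.setdefault(h.chrom, []).append(h.start)  # type: ignore[union-attr]
    a_by_chrom = {c: np.array(sorted(v), dtype=np.int64) for c, v in a_by_chrom.items()}
    b_counts: dict[str, int] = {}
    for h in hits_b:
        b_counts[h.chrom] = b_counts.get(h.chrom, 0) + 1

    # per-chromosome placement slots for single-base hit positions
    seg_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in segments:
        seg_by_chrom.setdefault(chrom, []).append((s, e))

    per_chrom_dists: list[np.ndarray] = []
    for chrom, nb in b_counts.items():
        pos_a = a_by_chrom.get(chrom)
        if pos_a is None or pos_a.size == 0 or nb == 0:
            continue
        slots = seg_by_chrom.get(chrom)
        if not slots:
            raise ValueError(f"universe has no territory on chromosome {chrom}")
        starts = np.array([s for s, _ in slots], dtype=np.int64)
        lens = np.array([e - s for s, e in slots], dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(lens)])
        draws = rng.integers(0, cum[-1], size=(n_perm, nb))
        seg_idx = np.searchsorted(cum, draws, side="right") - 1
        b_null = starts[seg_idx] + (draws - cum[seg_idx])
        b_null.sort(axis=1)
        # nearest |b - a| per permutation, vectorized
        idx = np.sum(b_null[:, :, None] <= pos_a[None, None, :], axis=1)
        left = np.take_along_axis(
            b_null, np.clip(idx - 1, 0, nb - 1), axis=1
        )
        right = np.take_along_axis(b_null, np.clip(idx, 0, nb - 1), axis=1)
        d_left = np.where(idx > 0, np.abs(pos_a[None, :] - left), np.iinfo(np.int64).max)
        d_right = np.where(idx < nb, np.abs(right - pos_a[None, :]), np.iinfo(np.int64).max)
        per_chrom_dists.append(np.minimum(d_left, d_right))

    if not per_chrom_dists:
        raise ValueError("no chromosome carries both a-hits and b-hits")
    null = np.concatenate(per_chrom_dists, axis=1).mean(axis=1)

    return PermutationResult(
        observed_statistic=float(observed),
        null_samples=null.astype(float),
        empirical_p=_empirical_p(observed, null, "less"),
        n_perm=n_perm,
        seed=seed,
        alternative="less",
    )


# ---------------------------------------------------------------------------
# Exact tests


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError("contingency counts must be non-negative integers")


def fisher_exact(table) -> tuple[float, float]:
    """Fisher's exact test for a 2×2 table; returns (odds ratio, two-sided p).

    The two-sided p sums, over all tables with the observed margins, the
    hypergeometric point probabilities that do not exceed the observed
    table's. The odds ratio is the sample ``ad/bc`` (``inf`` when ``bc = 0``
    and ``ad > 0``; 1 when both products are 0).
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        (a, b), (c, d) = table
    t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    r1, c1 = a + b, a + c
    ad, bc = a * d, b * c
    if bc == 0:
        odds = float("inf") if ad > 0 else 1.0
    else:
        odds = ad / bc
    if n == 0:
        return odds, 1.0
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return odds, min(1.0, p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Differential count test


def _effective_library_sizes(mat: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Median-of-ratios effective library sizes (geometric-mean reference).

    Robust to composition bias from asymmetric strong effects; preserves
    the overall scale of the raw totals so CPM values stay comparable.
    """
    positive = (mat > 0).all(axis=1)
    if positive.sum() < 10:
        return totals
    sub = mat[positive]
    ref = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / ref[:, None], axis=0)
    eff = factors / np.exp(np.log(factors).mean())  # geometric mean 1
    return eff * np.exp(np.log(totals).mean())


def differential_count_test(
    counts: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Two-group differential test on a feature × sample count table.

    Normalized abundances are counts per million (CPM) of the effective
    library size. Per feature:

    * ``log2fc`` = log2((mean CPM in a + pseudocount) / (mean CPM in b +
      pseudocount)) — positive means higher in group a;
    * ``p`` from an exact conditional binomial test: conditioned on the
      feature's pooled raw count, the group-a share is binomial with null
      success probability equal to group a's share of the total library;
    * ``q`` = Benjamini–Hochberg over all features.

    Library sizes are *effective* sizes: raw column totals rescaled by
    median-of-ratios factors (each sample's median ratio to the per-feature
    geometric-mean reference, computed over features with no zero count).
    This removes the composition bias that raw totals suffer when strong
    asymmetric differential features are present; when fewer than 10
    features are zero-free the raw totals are used as-is.

    All-zero features get ``p = 1`` and ``log2fc = 0``. A zero library size
    is an error.
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    if not samples_a or not samples_b:
        raise ValueError("each group needs at least one sample")
    sub = counts[samples_a + samples_b]
    if (sub.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    lib = sub.sum(axis=0).to_numpy(dtype=float)
    if (lib == 0).any():
        zero = [s for s, l in zip(samples_a + samples_b, lib) if l == 0]
        raise ValueError(f"zero library size for samples: {zero}")
    lib = _effective_library_sizes(sub.to_numpy(dtype=float), lib)
    cpm = sub.to_numpy(dtype=float) / lib[None, :] * 1e6
    na = len(samples_a)
    mean_a = cpm[:, :na].mean(axis=1)
    mean_b = cpm[:, na:].mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    pooled_a = sub.iloc[:, :na].sum(axis=1).to_numpy(dtype=np.int64)
    pooled_all = sub.sum(axis=1).to_numpy(dtype=np.int64)
    p_null = lib[:na].sum() / lib.sum()
    pvals = np.ones(len(sub))
    for i, (k, ntot) in enumerate(zip(pooled_a, pooled_all)):
        if ntot == 0:
            log2fc[i] = 0.0
            continue
        pvals[i] = stats.binomtest(int(k), int(ntot), p_null, alternative="two-sided").pvalue
    qvals = bh_fdr(pvals)
    return pd.DataFrame(
        {"log2fc": log2fc, "p": pvals, "q": qvals}, index=counts.index
    )
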