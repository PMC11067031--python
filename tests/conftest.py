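"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive every interval operation by
exhaustive O(n²) pairwise comparison, independent of the package's sweep
implementations, so the two routes can be checked against each other.
"""

from __future__ import annotations

import numpy as np
import pytest

from bindweave.intervals import GenomicInterval, PeakSet


# ---------------------------------------------------------------------------
# Brute-force oracles


def bf_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def bf_merge(intervals) -> list[tuple[str, int, int]]:
    """Merge >= 1 bp-overlapping intervals by direct scanning."""
    out: list[list] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if out and out[-1][0] == iv.chrom and iv.start < out[-1][2]:
            out[-1][2] = max(out[-1][2], iv.end)
        else:
            out.append([iv.chrom, iv.start, iv.end])
    return [tuple(x) for x in out]


def bf_consensus(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> list[tuple[str, int, int]]:
    members = set()
    for ai in a:
        for bj in b:
            if bf_overlap(ai, bj) >= min_overlap:
                members.add((ai.chrom, ai.start, ai.end))
                members.add((bj.chrom, bj.start, bj.end))
    return bf_merge(GenomicInterval(c, s, e) for c, s, e in members)


def bf_count_overlapping(query: PeakSet, reference: PeakSet, min_overlap: int = 1):
    flags = [
        any(bf_overlap(q, r) >= min_overlap for r in reference) for q in query
    ]
    return sum(flags), flags


def bf_shared_specific(a: PeakSet, b: PeakSet):
    a_hit = [any(bf_overlap(x, y) > 0 for y in b) for x in a]
    b_hit = [any(bf_overlap(y, x) > 0 for x in a) for y in b]
    shared = bf_merge(
        [iv for iv, f in zip(a, a_hit) if f] + [iv for iv, f in zip(b, b_hit) if f]
    )
    a_only = [iv for iv, f in zip(a, a_hit) if not f]
    b_only = [iv for iv, f in zip(b, b_hit) if not f]
    return shared, a_only, b_only


def bf_genes_within(peaks: PeakSet, ann, max_distance: int):
    result = {}
    for row in ann.table.itertuples(index=False):
        best = None
        for p in peaks:
            if p.chrom != row.chrom:
                continue
            if p.start < row.end and row.start < p.end:
                d = 0
            elif p.end <= row.start:
                d = row.start - p.end
            else:
                d = p.start - row.end
            if best is None or d < best:
                best = d
        if best is not None and best <= max_distance:
            result[row.gene_id] = best
    return result


# ---------------------------------------------------------------------------
# Random instance builders


def random_peakset(
    rng: np.random.Generator,
    n: int,
    genome: dict[str, int],
    max_width: int = 500,
    label: str = "",
) -> PeakSet:
    chroms = list(genome)
    ivs = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        width = int(rng.integers(1, max_width))
        start = int(rng.integers(0, max(1, genome[chrom] - width)))
        ivs.append(GenomicInterval(chrom, start, start + width))
    return PeakSet(ivs, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(20240422)


@pytest.fixture
def toy_genome_sizes():
    return {"chr1": 100_000, "chr2": 60_000}
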