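"""Genomic interval model, BED/annotation I/O, and interval set algebra.

All coordinates are 0-based, half-open ``[start, end)`` — the native BED
convention. Adjacent intervals (``[x, y)`` and ``[y, z)``) never overlap.
Any 1-based annotation source must be converted at the reader boundary.

The operations here are the backbone of the integration analyses:
consensus binding-site identification from two orthogonal assays,
binding-site-to-gene assignment, genomic feature-class distribution
against a genome background, and shared/genotype-specific partitioning
of accessibility peak sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("bindweave")

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic range ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases (0 if different chromosomes or disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> Optional[int]:
        """Bases between two intervals on one chromosome; 0 when they overlap
        or abut; None if on different chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlap(other) > 0:
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


class PeakSet:
    """An ordered collection of :class:`GenomicInterval`, sorted by
    (chrom, start, end). Merging is on demand, never silent."""

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = ""):
        self.intervals: tuple[GenomicInterval, ...] = tuple(
            sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        )
        self.label = label
        self._arrays: Optional[dict[str, tuple[np.ndarray, np.ndarray]]] = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"PeakSet({len(self)} intervals, label={self.label!r})"

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, start-sorted; cached."""
        if self._arrays is None:
            arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for chrom in self.chroms():
                ivs = [iv for iv in self.intervals if iv.chrom == chrom]
                arrays[chrom] = (
                    np.array([iv.start for iv in ivs], dtype=np.int64),
                    np.array([iv.end for iv in ivs], dtype=np.int64),
                )
            self._arrays = arrays
        return self._arrays

    def total_bases(self) -> int:
        """Bases covered by the merged set."""
        return sum(len(iv) for iv in self.merge())

    def merge(self, label: Optional[str] = None) -> "PeakSet":
        """Merge overlapping (>= 1 bp) intervals into maximal runs.
        Abutting half-open intervals are kept separate."""
        merged: list[GenomicInterval] = []
        for iv in self.intervals:
            if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
                last = merged[-1]
                merged[-1] = GenomicInterval(
                    last.chrom, last.start, max(last.end, iv.end)
                )
            else:
                merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
        return PeakSet(merged, label=label if label is not None else self.label)


def read_bed(path: str | Path, label: str = "") -> PeakSet:
    """Read a BED3+ file into a :class:`PeakSet`.

    Raises ``ValueError`` naming the 1-based line number for malformed
    lines (too few fields, non-numeric coordinates, start >= end, negative
    coordinates). Lines starting with ``track``, ``browser`` or ``#`` are
    skipped; blank lines are ignored.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(intervals, label=label or path.stem)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as BED6 (name/score default to '.' / '0')."""
    with open(path, "w") as fh:
        for iv in peaks:
            score = "0" if iv.score is None else format(iv.score, "g")
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column (chrom, length) TSV into a dict."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected chrom<TAB>length")
            sizes[fields[0]] = int(fields[1])
    return sizes


# ---------------------------------------------------------------------------
# Gene annotation


class GeneAnnotation:
    """Per-gene table: gene_id, chrom, strand, start, end, tss.

    The TSS must equal the gene start on the + strand and the gene end on
    the − strand (half-open convention: the − strand TSS base is ``end - 1``
    but is recorded as ``end`` consistently by the converter; what matters
    downstream are gene-body distances, which use start/end).
    """

    COLUMNS = ["gene_id", "chrom", "strand", "start", "end", "tss"]

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
        if table["gene_id"].duplicated().any():
            dups = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        bad_strand = ~table["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise ValueError("gene strand must be '+' or '-'")
        plus = table["strand"] == "+"
        if not (table.loc[plus, "tss"] == table.loc[plus, "start"]).all():
            raise ValueError("TSS must equal gene start on the + strand")
        if not (table.loc[~plus, "tss"] == table.loc[~plus, "end"]).all():
            raise ValueError("TSS must equal gene end on the - strand")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "GeneAnnotation":
        df = pd.DataFrame(list(records), columns=cls.COLUMNS)
        return cls(df)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneAnnotation":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def chroms(self) -> list[str]:
        return sorted(self.table["chrom"].unique())


@dataclass
class FeatureClassScheme:
    """Windows defining genomic feature classes (multi-label; classes may
    overlap, so per-class fractions can sum to more than 1).

    Defaults: promoter = TSS −1000..+200 (strand-aware), TSS class = TSS ± 100.
    Exon/intron classes require an exon BED; an enhancer class requires a
    user-supplied BED.
    """

    promoter_upstream: int = 1000
    promoter_downstream: int = 200
    tss_halfwidth: int = 100

    def __post_init__(self) -> None:
        if min(self.promoter_upstream, self.promoter_downstream, self.tss_halfwidth) <= 0:
            raise ValueError("feature-class windows must be positive")


# ---------------------------------------------------------------------------
# Set algebra


def _qualifying_pairs(a: PeakSet, b: PeakSet, min_overlap: int) -> list[tuple[int, int]]:
    """All (i, j) index pairs with overlap(a[i], b[j]) >= min_overlap.

    Sweep per chromosome with numpy broadcasting in chunks; inputs at the
    scale used here (thousands) stay cheap.
    """
    pairs: list[tuple[int, int]] = []
    a_idx = {chrom: [] for chrom in a.chroms()}
    b_idx = {chrom: [] for chrom in b.chroms()}
    for i, iv in enumerate(a.intervals):
        a_idx[iv.chrom].append(i)
    for j, iv in enumerate(b.intervals):
        b_idx[iv.chrom].append(j)
    for chrom in set(a_idx) & set(b_idx):
        ia = np.array(a_idx[chrom])
        jb = np.array(b_idx[chrom])
        a_s, a_e = a.by_chrom()[chrom]
        b_s, b_e = b.by_chrom()[chrom]
        # overlap matrix in chunks to bound memory
        chunk = max(1, int(4e6) // max(1, len(jb)))
        for lo in range(0, len(ia), chunk):
            hi = min(lo + chunk, len(ia))
            ov = np.minimum(a_e[lo:hi, None], b_e[None, :]) - np.maximum(
                a_s[lo:hi, None], b_s[None, :]
            )
            ii, jj = np.nonzero(ov >= min_overlap)
            pairs.extend(zip(ia[lo + ii].tolist(), jb[jj].tolist()))
    return pairs


def intersect_consensus(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> PeakSet:
    """Consensus regions supported by both assays.

    Pools every a-interval that overlaps a b-interval by >= ``min_overlap``
    together with all b-intervals it touches at that threshold, then merges
    the pooled intervals (>= 1 bp) into maximal clusters. Each cluster is one
    consensus site; output is sorted and non-overlapping. Cluster count is
    symmetric in the argument order.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    pairs = _qualifying_pairs(a, b, min_overlap)
    members: set[GenomicInterval] = set()
    for i, j in pairs:
        ai, bj = a.intervals[i], b.intervals[j]
        members.add(GenomicInterval(ai.chrom, ai.start, ai.end))
        members.add(GenomicInterval(bj.chrom, bj.start, bj.end))
    return PeakSet(members, label=f"consensus({a.label},{b.label})").merge()


def count_overlapping(
    query: PeakSet, reference: PeakSet, min_overlap: int = 1
) -> tuple[int, np.ndarray]:
    """Number of query intervals with >= 1 qualifying reference overlap.

    Returns ``(count, flags)`` with ``flags`` aligned 1:1 to ``query`` order.
    The ``min_overlap == 1`` path is vectorized (sorted-array counting) and is
    the one the permutation tests lean on.
    """
    flags = np.zeros(len(query), dtype=bool)
    ref = reference.by_chrom()
    if min_overlap == 1:
        ref_sorted = {
            c: (np.sort(s), np.sort(e)) for c, (s, e) in ref.items()
        }
        for i, iv in enumerate(query.intervals):
            if iv.chrom not in ref_sorted:
                continue
            starts, ends = ref_sorted[iv.chrom]
            n_start_before_qend = np.searchsorted(starts, iv.end, side="left")
            n_end_before_qstart = np.searchsorted(ends, iv.start, side="right")
            flags[i] = n_start_before_qend > n_end_before_qstart
    else:
        for i, iv in enumerate(query.intervals):
            if iv.chrom not in ref:
                continue
            s, e = ref[iv.chrom]
            ov = np.minimum(iv.end, e) - np.maximum(iv.start, s)
            flags[i] = bool((ov >= min_overlap).any())
    return int(flags.sum()), flags


def overlap_flags_sorted(
    q_starts: np.ndarray, q_ends: np.ndarray, r_starts_sorted: np.ndarray, r_ends_sorted: np.ndarray
) -> np.ndarray:
    """Vectorized >=1 bp overlap flags for arrays on one chromosome.

    ``r_starts_sorted``/``r_ends_sorted`` must each be individually sorted.
    Used by the permutation machinery; semantics identical to
    :func:`count_overlapping` with ``min_overlap=1``.
    """
    n_start_before = np.searchsorted(r_starts_sorted, q_ends, side="left")
    n_end_before = np.searchsorted(r_ends_sorted, q_starts, side="right")
    return n_start_before > n_end_before


def genes_within(
    peaks: PeakSet, ann: GeneAnnotation, max_distance: int = 1000
) -> dict[str, int]:
    """Genes whose gene body lies within ``max_distance`` bases of any peak.

    Distance is the gap between the peak and the gene-body interval
    (0 when they overlap or abut). Returns ``{gene_id: min_distance}``.
    Peaks on chromosomes absent from the annotation are skipped with a
    logged warning.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    result: dict[str, int] = {}
    ann_chroms = set(ann.chroms())
    skipped = 0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in peaks:
        if iv.chrom not in ann_chroms:
            skipped += 1
            continue
        by_chrom.setdefault(iv.chrom, []).append(iv)
    if skipped:
        logger.warning("genes_within: %d peaks on chromosomes absent from annotation", skipped)
    for chrom, ivs in by_chrom.items():
        genes = ann.table[ann.table["chrom"] == chrom]
        if genes.empty:
            continue
        g_start = genes["start"].to_numpy()
        g_end = genes["end"].to_numpy()
        g_id = genes["gene_id"].to_numpy()
        p_start = np.array([iv.start for iv in ivs])
        p_end = np.array([iv.end for iv in ivs])
        # gap matrix: 0 on overlap/abutment, else positive separation
        gap = np.maximum(
            0,
            np.maximum(g_start[None, :] - p_end[:, None], p_start[:, None] - g_end[None, :]),
        )
        min_gap = gap.min(axis=0)
        for gid, d in zip(g_id, min_gap):
            if d <= max_distance:
                d = int(d)
                if gid not in result or d < result[gid]:
                    result[gid] = d
    return result


def _class_territory(
    ann: GeneAnnotation,
    scheme: FeatureClassScheme,
    genome_sizes: Mapping[str, int],
    exons: Optional[PeakSet] = None,
    enhancers: Optional[PeakSet] = None,
) -> dict[str, PeakSet]:
    """Merged genomic territory for each feature class."""
    territories: dict[str, list[GenomicInterval]] = {
        "promoter": [],
        "tss": [],
        "gene_body": [],
    }
    for row in ann.table.itertuples(index=False):
        size = genome_sizes.get(row.chrom)
        if size is None:
            raise ValueError(f"genome_sizes missing chromosome {row.chrom}")
        if row.strand == "+":
            p0, p1 = row.tss - scheme.promoter_upstream, row.tss + scheme.promoter_downstream
        else:
            p0, p1 = row.tss - scheme.promoter_downstream, row.tss + scheme.promoter_upstream
        t0, t1 = row.tss - scheme.tss_halfwidth, row.tss + scheme.tss_halfwidth
        for key, (lo, hi) in (("promoter", (p0, p1)), ("tss", (t0, t1))):
            lo, hi = max(0, lo), min(size, hi)
            if lo < hi:
                territories[key].append(GenomicInterval(row.chrom, lo, hi))
        territories["gene_body"].append(GenomicInterval(row.chrom, row.start, row.end))
    out = {k: PeakSet(v).merge() for k, v in territories.items() if k != "gene_body"}
    gene_body = PeakSet(territories["gene_body"]).merge()
    if exons is not None:
        out["exon"] = exons.merge()
        # introns: gene body minus exon territory
        introns: list[GenomicInterval] = []
        ex = out["exon"].by_chrom()
        for iv in gene_body:
            cuts = []
            if iv.chrom in ex:
                s, e = ex[iv.chrom]
                keep = (s < iv.end) & (e > iv.start)
                cuts = sorted(zip(np.maximum(s[keep], iv.start), np.minimum(e[keep], iv.end)))
            pos = iv.start
            for cs, ce in cuts:
                if cs > pos:
                    introns.append(GenomicInterval(iv.chrom, pos, cs))
                pos = max(pos, ce)
            if pos < iv.end:
                introns.append(GenomicInterval(iv.chrom, pos, iv.end))
        out["intron"] = PeakSet(introns).merge()
    # intergenic: complement of gene bodies over the genome
    intergenic: list[GenomicInterval] = []
    gb = gene_body.by_chrom()
    for chrom, size in genome_sizes.items():
        pos = 0
        if chrom in gb:
            for s, e in zip(*gb[chrom]):
                if s > pos:
                    intergenic.append(GenomicInterval(chrom, pos, int(s)))
                pos = max(pos, int(e))
        if pos < size:
            intergenic.append(GenomicInterval(chrom, pos, size))
    out["intergenic"] = PeakSet(intergenic).merge()
    if enhancers is not None:
        out["enhancer"] = enhancers.merge()
    return out


def classify_feature_distribution(
    peaks: PeakSet,
    ann: GeneAnnotation,
    scheme: FeatureClassScheme,
    genome_sizes: Mapping[str, int],
    exons: Optional[PeakSet] = None,
    enhancers: Optional[PeakSet] = None,
) -> pd.DataFrame:
    """Distribution of peaks over genomic feature classes vs. genome background.

    A peak belongs to a class if its midpoint lies in the class territory
    (multi-label: one peak can hit several classes, so fractions may sum to
    more than 1). The background fraction is the class territory's share of
    genome bases; significance is a two-sided binomial test of the observed
    peak count against that background fraction.
    """
    if len(peaks) == 0:
        raise ValueError("cannot classify an empty peak set")
    territories = _class_territory(ann, scheme, genome_sizes, exons=exons, enhancers=enhancers)
    genome_total = sum(genome_sizes.values())
    midpoints = PeakSet(
        [
            GenomicInterval(iv.chrom, (iv.start + iv.end) // 2, (iv.start + iv.end) // 2 + 1)
            for iv in peaks
        ]
    )
    rows = []
    for cls, terr in territories.items():
        k, _ = count_overlapping(midpoints, terr)
        bg = terr.total_bases() / genome_total
        if 0 < bg < 1:
            p = stats.binomtest(k, len(peaks), bg, alternative="two-sided").pvalue
        else:
            p = 1.0
        rows.append(
            {
                "feature_class": cls,
                "n_peaks": k,
                "observed_fraction": k / len(peaks),
                "background_fraction": bg,
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def shared_and_specific(a: PeakSet, b: PeakSet) -> tuple[PeakSet, PeakSet, PeakSet]:
    """Partition two peak sets into shared clusters and set-specific peaks.

    Shared is defined by >= 1 bp cross-set overlap; shared regions are
    returned as merged clusters. Every input interval lands in exactly one
    of the three outputs: inside a shared cluster, in ``a_only``, or in
    ``b_only``.
    """
    _, a_flags = count_overlapping(a, b)
    _, b_flags = count_overlapping(b, a)
    shared_members = [iv for iv, f in zip(a.intervals, a_flags) if f]
    shared_members += [iv for iv, f in zip(b.intervals, b_flags) if f]
    shared = PeakSet(shared_members, label="shared").merge()
    a_only = PeakSet(
        [iv for iv, f in zip(a.intervals, a_flags) if not f], label=f"{a.label}_only"
    )
    b_only = PeakSet(
        [iv for iv, f in zip(b.intervals, b_flags) if not f], label=f"{b.label}_only"
    )
    return shared, a_only, b_only
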