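"""Motif scanning and heterotypic spacing.

Built-in motifs are the IUPAC consensus patterns central to the biology of
the PML::RARA / GATA2 axis: the retinoic-acid response element half site
(RGKTCA), the GATA factor motif (WGATAR), and the DR5 element — a direct
repeat of two RARE half sites on the same strand separated by exactly 5 bp.

Scanning reports every match on both strands in plus-strand coordinates,
with no greedy suppression of overlapping hits. A position-weight-matrix
mode with a log-odds threshold is available for motifs that are not well
captured by a hard consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import yaml

from .intervals import GenomicInterval, PeakSet

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYKMSWBDHVN", "TGCAYRMKSWVHDBN")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    """A named motif: either an IUPAC consensus string or a PWM.

    PWM columns are base probability distributions (A,C,G,T rows summing
    to 1) transformed to log-odds against a uniform background; a window
    scores a hit when its log-odds score reaches ``threshold_frac`` of the
    maximum attainable score. Both strands are always scanned.
    """

    name: str
    iupac: Optional[str] = None
    pwm: Optional[np.ndarray] = None  # shape (4, width), columns sum to 1
    threshold_frac: float = 0.8

    def __post_init__(self) -> None:
        if (self.iupac is None) == (self.pwm is None):
            raise ValueError("exactly one of iupac or pwm must be given")
        if self.iupac is not None:
            self.iupac = self.iupac.upper()
            bad = set(self.iupac) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC symbols {sorted(bad)} in {self.name}")
        else:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.shape[0] != 4:
                raise ValueError("PWM must have 4 rows (A,C,G,T)")
            if not np.allclose(self.pwm.sum(axis=0), 1.0):
                raise ValueError("PWM columns must sum to 1")
            if not 0 < self.threshold_frac <= 1:
                raise ValueError("threshold_frac must be in (0, 1]")

    @property
    def width(self) -> int:
        return len(self.iupac) if self.iupac is not None else self.pwm.shape[1]


@dataclass(frozen=True)
class MotifHit:
    """One stranded motif occurrence, in plus-strand coordinates."""

    chrom: str
    start: int
    strand: str
    motif: str
    score: Optional[float] = None


@dataclass
class SpacingSummary:
    """Nearest-neighbor distances between two motif hit classes."""

    n_pairs: int
    distances: np.ndarray
    mean_spacing: float
    n_excluded: int = 0
    p_closer_than_chance: Optional[float] = None


# built-in library
RARE_HALF = MotifModel("RARE_half", iupac="RGKTCA")
GATA = MotifModel("GATA", iupac="WGATAR")
DR5_SPACER = 5
BUILTIN_MOTIFS: dict[str, MotifModel] = {m.name: m for m in (RARE_HALF, GATA)}


def load_motifs(path: str | Path) -> dict[str, MotifModel]:
    """Load a named motif library from YAML.

    Each entry is either ``name: IUPACSTRING`` or a mapping with keys
    ``pwm`` (4×w list of lists) and optional ``threshold_frac``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    motifs: dict[str, MotifModel] = {}
    for name, val in raw.items():
        if isinstance(val, str):
            motifs[name] = MotifModel(name, iupac=val)
        else:
            motifs[name] = MotifModel(
                name,
                pwm=np.array(val["pwm"], dtype=float),
                threshold_frac=float(val.get("threshold_frac", 0.8)),
            )
    return motifs


def _encode(seq: str) -> np.ndarray:
    """Sequence → integer codes A=0 C=1 G=2 T=3, N/other=4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def _match_starts_consensus(codes: np.ndarray, iupac: str) -> np.ndarray:
    """Start offsets of exact consensus matches (N in sequence never matches)."""
    w = len(iupac)
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for offset, symbol in enumerate(iupac):
        allowed = IUPAC[symbol]
        window = codes[offset : offset + n]
        pos_ok = np.zeros(n, dtype=bool)
        for base in allowed:
            pos_ok |= window == _BASE_INDEX[base]
        ok &= pos_ok
    return np.nonzero(ok)[0].astype(np.int64)


def _match_starts_pwm(codes: np.ndarray, pwm: np.ndarray, threshold_frac: float):
    """(starts, scores) of PWM windows scoring >= threshold_frac * max score."""
    w = pwm.shape[1]
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    logodds = np.log2(np.maximum(pwm, 1e-9) / 0.25)
    # N (code 4) scores -inf so it never matches
    lut = np.vstack([logodds, np.full((1, w), -np.inf)])
    score = np.zeros(n)
    for offset in range(w):
        score += lut[codes[offset : offset + n], offset]
    threshold = threshold_frac * logodds.max(axis=0).sum()
    keep = score >= threshold
    return np.nonzero(keep)[0].astype(np.int64), score[keep]


def scan(sequence: str, motif: MotifModel, chrom: str = "seq") -> list[MotifHit]:
    """All occurrences of ``motif`` on both strands of ``sequence``.

    Hits are reported in plus-strand coordinates (start of the matched
    window), sorted by start then strand; overlapping hits are all kept.
    A motif longer than the sequence yields an empty list.
    """
    seq = sequence.upper()
    L = len(seq)
    if L < motif.width:
        return []
    hits: list[MotifHit] = []
    fwd = _encode(seq)
    rev = _encode(reverse_complement(seq))
    if motif.iupac is not None:
        for start in _match_starts_consensus(fwd, motif.iupac):
            hits.append(MotifHit(chrom, int(start), "+", motif.name))
        for start in _match_starts_consensus(rev, motif.iupac):
            hits.append(MotifHit(chrom, int(L - start - motif.width), "-", motif.name))
    else:
        starts, scores = _match_starts_pwm(fwd, motif.pwm, motif.threshold_frac)
        for start, sc in zip(starts, scores):
            hits.append(MotifHit(chrom, int(start), "+", motif.name, score=float(sc)))
        starts, scores = _match_starts_pwm(rev, motif.pwm, motif.threshold_frac)
        for start, sc in zip(starts, scores):
            hits.append(
                MotifHit(chrom, int(L - start - motif.width), "-", motif.name, score=float(sc))
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_dr5(sequence: str, chrom: str = "seq") -> list[MotifHit]:
    """DR5 elements: two same-strand RARE half sites with exactly 5 bp between.

    The reported start is the start of the upstream half site in the motif's
    own orientation: the left half for plus-strand elements, and (in
    plus-strand coordinates) the right half — ``pair start + 11`` — for
    minus-strand elements.
    """
    half = RARE_HALF
    offset = half.width + DR5_SPACER  # 11
    hits = scan(sequence, half, chrom=chrom)
    by_strand: dict[str, set[int]] = {"+": set(), "-": set()}
    for h in hits:
        by_strand[h.strand].add(h.start)
    out: list[MotifHit] = []
    for strand, starts in by_strand.items():
        for s in sorted(starts):
            if s + offset in starts:
                coord = s if strand == "+" else s + offset
                out.append(MotifHit(chrom, coord, strand, "DR5"))
    out.sort(key=lambda h: (h.start, h.strand))
    return out


def _get_sequence(genome, chrom: str) -> str:
    """Fetch one chromosome from a dict-of-strings or a pyfaidx.Fasta."""
    seq = genome[chrom]
    return seq if isinstance(seq, str) else str(seq)


def peak_motif_fraction(
    peaks: PeakSet,
    genome,
    motif: Union[MotifModel, str],
) -> tuple[float, np.ndarray]:
    """Fraction of peaks containing >= 1 motif hit anywhere inside the peak.

    ``motif`` may be a :class:`MotifModel` or the string ``"DR5"`` for the
    composite direct-repeat element. Returns (fraction, per-peak flags in
    peak order). A peak extending past its chromosome end is an error naming
    the peak.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    flags = np.zeros(len(peaks), dtype=bool)
    cache: dict[str, str] = {}
    for i, iv in enumerate(peaks):
        if iv.chrom not in cache:
            cache[iv.chrom] = _get_sequence(genome, iv.chrom)
        seq = cache[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(
                f"peak {iv.chrom}:{iv.start}-{iv.end} extends past chromosome end ({len(seq)})"
            )
        window = seq[iv.start : iv.end]
        if isinstance(motif, str) and motif.upper() == "DR5":
            found = bool(scan_dr5(window))
        else:
            found = bool(scan(window, motif))
        flags[i] = found
    return float(flags.mean()), flags


def hits_to_bed(hits: Sequence[MotifHit], width: Optional[int] = None) -> PeakSet:
    """MotifHit list → BED6-writable PeakSet (score column = PWM score)."""
    ivs = []
    for h in hits:
        w = width if width is not None else 1
        ivs.append(
            GenomicInterval(h.chrom, h.start, h.start + w, name=h.motif, score=h.score, strand=h.strand)
        )
    return PeakSet(ivs, label="motif_hits")


def heterotypic_spacing(
    hits_a: Sequence[MotifHit],
    hits_b: Sequence[MotifHit],
    restrict_to: Optional[PeakSet] = None,
    mode: str = "start",
) -> SpacingSummary:
    """Nearest-neighbor distances from each a-hit to the closest b-hit.

    Distance is the absolute start-to-start offset (``mode="start"``,
    default) or midpoint-to-midpoint with a supplied motif width
    (``mode="midpoint"`` treats starts as midpoints), strand-agnostic,
    same-chromosome only. When ``restrict_to`` is given only hits lying
    entirely within those intervals are considered (motif width taken as 1
    for containment of the start coordinate). A-hits with no
    same-chromosome b-hit are excluded and counted in ``n_excluded``.
    """
    if not hits_a and not hits_b:
        raise ValueError("both hit lists are empty")
    if mode not in {"start", "midpoint"}:
        raise ValueError("mode must be 'start' or 'midpoint'")

    def _filter(hits: Sequence[MotifHit]) -> list[MotifHit]:
        if restrict_to is None:
            return list(hits)
        kept = []
        regions = restrict_to.by_chrom()
        for h in hits:
            if h.chrom not in regions:
                continue
            s, e = regions[h.chrom]
            if bool(((s <= h.start) & (h.start < e)).any()):
                kept.append(h)
        return kept

    a = _filter(hits_a)
    b = _filter(hits_b)
    if not a:
        raise ValueError("no a-hits remain after filtering")
    b_by_chrom: dict[str, np.ndarray] = {}
    for h in b:
        b_by_chrom.setdefault(h.chrom, [])
    for h in b:
        b_by_chrom[h.chrom].append(h.start)  # type: ignore[attr-defined]
    b_by_chrom = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in b_by_chrom.items()}
    distances: list[int] = []
    excluded = 0
    for h in a:
        pos = b_by_chrom.get(h.chrom)
        if pos is None or pos.size == 0:
            excluded += 1
            continue
        idx = np.searchsorted(pos, h.start)
        best = np.inf
        if idx < pos.size:
            best = min(best, abs(int(pos[idx]) - h.start))
        if idx > 0:
            best = min(best, abs(h.start - int(pos[idx - 1])))
        distances.append(int(best))
    if not distances:
        raise ValueError("no a-hit has a same-chromosome b-hit")
    arr = np.array(distances, dtype=np.int64)
    return SpacingSummary(
        n_pairs=arr.size,
        distances=arr,
        mean_spacing=float(arr.mean()),
        n_excluded=excluded,
    )
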