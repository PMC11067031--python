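"""Synthetic genomes, peak sets, and count tables with planted ground truth.

Every downstream stage of the pipeline — consensus binding-site calling,
motif content and spacing, differential accessibility/expression
classification, binding-dependence contrasts, and interactome filtering —
is exercised against data generated here, where the truth is known by
construction:

* genomes are i.i.d. nucleotides at a configured GC fraction, with motif
  instances (and heterotypic motif *pairs* at controlled spacing) planted
  at recorded coordinates; background windows that happen to match a
  planted consensus are rejection-resampled so planted occurrences are the
  only ones;
* dual-assay peak sets are built with a controlled pairwise overlap
  fraction, recording the true consensus intervals;
* count tables are negative binomial (mean/dispersion parameterization)
  with a planted fraction of differential features at a configured log2
  fold-change, and a planted "binding-dependent" subset whose effect is
  present in wild-type groups but absent in the DNA-binding-dead (C88A)
  group. Spectral-count tables for the proximity-labeling design reuse the
  same machinery at low means.

Each artifact draws from its own RNG stream derived from the master seed by
a fixed offset, so adding an artifact never perturbs earlier draws. The
same config + seed reproduce byte-identical FASTA/BED/TSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, PeakSet
from .motifscan import BUILTIN_MOTIFS, IUPAC, MotifModel, reverse_complement, scan

logger = logging.getLogger("bindweave")

# fixed RNG stream offsets per artifact
_STREAM_GENOME = 0
_STREAM_PEAKS = 1
_STREAM_COUNTS = 2


@dataclass
class MotifPlant:
    """A planting instruction: ``count`` instances of ``motif``; when
    ``pair_with`` is set, each instance is a heterotypic pair with the
    second motif planted downstream at ``spacing`` (start-to-start bases,
    either a fixed int or a ``(mean, sd)`` normal draw, same strand)."""

    motif: str = "GATA"
    count: int = 0
    pair_with: Optional[str] = None
    spacing: Union[int, tuple[float, float], None] = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("plant count must be >= 0")
        if self.pair_with is not None and self.spacing is None:
            raise ValueError("paired plants need a spacing rule")


@dataclass
class PeakParams:
    n_peaks: int = 1000
    mean_width: int = 200
    overlap_fraction: float = 0.5
    motif_anchor_fraction: float = 0.0  # fraction of A peaks centered on a plant

    def __post_init__(self) -> None:
        if self.n_peaks < 0 or self.mean_width <= 0:
            raise ValueError("n_peaks must be >= 0 and mean_width > 0")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if not 0 <= self.motif_anchor_fraction <= 1:
            raise ValueError("motif_anchor_fraction must be in [0, 1]")


@dataclass
class CountParams:
    """Negative-binomial count-table parameters.

    ``design`` selects the group layout: ``two_group`` (case vs control),
    ``binding`` (empty / WT / C88A, with a binding-dependent planted
    subset), or ``interactome`` (control / WT_N / WT_C / C88A spectral
    counts).
    """

    n_features: int = 2000
    n_samples: int = 4  # per group
    nb_mean: float = 100.0
    nb_dispersion: float = 0.1
    effect_log2fc: float = 2.0
    planted_fraction: float = 0.1
    binding_fraction: float = 0.5  # planted features that are binding-dependent
    design: str = "two_group"

    def __post_init__(self) -> None:
        if self.n_features < 0 or self.n_samples < 2:
            raise ValueError("need n_features >= 0 and >= 2 samples per group")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("NB mean and dispersion must be positive")
        if not 0 <= self.planted_fraction <= 1 or not 0 <= self.binding_fraction <= 1:
            raise ValueError("planted/binding fractions must be in [0, 1]")
        if self.design not in {"two_group", "binding", "interactome"}:
            raise ValueError(f"unknown design {self.design!r}")


@dataclass
class SynthConfig:
    genome_length: int = 1_000_000
    chrom_count: int = 2
    gc_fraction: float = 0.41
    motif_plants: list[MotifPlant] = field(default_factory=list)
    peak_params: PeakParams = field(default_factory=PeakParams)
    count_params: CountParams = field(default_factory=CountParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if self.chrom_count < 1:
            raise ValueError("chrom_count must be >= 1")
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SynthConfig":
        kwargs = dict(raw)
        if "motif_plants" in kwargs:
            plants = []
            for p in kwargs["motif_plants"]:
                p = dict(p)
                if isinstance(p.get("spacing"), list):
                    p["spacing"] = tuple(p["spacing"])
                plants.append(MotifPlant(**p))
            kwargs["motif_plants"] = plants
        if "peak_params" in kwargs:
            kwargs["peak_params"] = PeakParams(**kwargs["peak_params"])
        if "count_params" in kwargs:
            kwargs["count_params"] = CountParams(**kwargs["count_params"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


@dataclass
class TruthRecord:
    """Planted ground truth emitted alongside the synthetic artifacts."""

    planted_motif_positions: list[tuple[str, int, str, str]] = field(default_factory=list)
    planted_pair_spacing: list[int] = field(default_factory=list)
    true_consensus_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    true_differential_features: list[tuple[str, int, float]] = field(default_factory=list)
    true_binding_dependent_features: list[str] = field(default_factory=list)
    true_interactors: list[str] = field(default_factory=list)
    true_binding_dependent_interactors: list[str] = field(default_factory=list)

    def validate(self) -> None:
        diff_ids = {f for f, _, _ in self.true_differential_features}
        if not set(self.true_binding_dependent_features) <= diff_ids:
            raise ValueError("binding-dependent features must be a subset of differential features")
        if not set(self.true_binding_dependent_interactors) <= set(self.true_interactors):
            raise ValueError("binding-dependent interactors must be a subset of interactors")

    def to_json(self, path: Optional[str | Path] = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        raw = json.loads(Path(path).read_text())
        rec = cls(**{k: [tuple(x) if isinstance(x, list) else x for x in v] for k, v in raw.items()})
        return rec


# ---------------------------------------------------------------------------
# Genome


def _chrom_layout(config: SynthConfig) -> dict[str, int]:
    base = config.genome_length // config.chrom_count
    sizes = {f"chr{i + 1}": base for i in range(config.chrom_count)}
    # remainder goes to the last chromosome
    sizes[f"chr{config.chrom_count}"] += config.genome_length - base * config.chrom_count
    return sizes


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)


def _concrete_instance(rng: np.random.Generator, iupac: str) -> str:
    return "".join(rng.choice(sorted(IUPAC[sym])) for sym in iupac)


def _motif_model(name: str) -> MotifModel:
    if name in BUILTIN_MOTIFS:
        return BUILTIN_MOTIFS[name]
    raise ValueError(f"unknown motif {name!r}; built-ins: {sorted(BUILTIN_MOTIFS)}")


class _Packer:
    """Non-overlapping slot allocation with a safety gap between plants."""

    GAP = 20

    def __init__(self, sizes: dict[str, int], rng: np.random.Generator):
        self.sizes = sizes
        self.rng = rng
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}

    def place(self, width: int, max_tries: int = 2000) -> tuple[str, int]:
        chroms = list(self.sizes)
        weights = np.array([self.sizes[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        for _ in range(max_tries):
            chrom = self.rng.choice(chroms, p=weights)
            size = self.sizes[chrom]
            if size <= width + 2 * self.GAP:
                continue
            start = int(self.rng.integers(self.GAP, size - width - self.GAP))
            slots = self.occupied[chrom]
            i = bisect_left(slots, (start, start + width))
            clash = False
            for j in (i - 1, i):
                if 0 <= j < len(slots):
                    s, e = slots[j]
                    if start - self.GAP < e and s < start + width + self.GAP:
                        clash = True
            if not clash:
                insort(slots, (start, start + width))
                return chrom, start
        raise ValueError(
            "infeasible packing: could not place all motif plants in the genome"
        )


def make_genome(config: SynthConfig) -> tuple[dict[str, str], TruthRecord]:
    """Generate chromosome sequences with planted motif instances.

    Returns ``(genome, truth)`` where ``genome`` maps chromosome name to
    sequence and ``truth.planted_motif_positions`` lists every plant as
    ``(chrom, start, strand, motif)``. Background windows matching a
    planted consensus (either strand) are rejection-resampled, so the
    planted occurrences are the only exact matches in the emitted genome.
    Raises ``ValueError`` before emitting anything if the plants cannot be
    packed into the genome.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(_STREAM_GENOME,)))
    sizes = _chrom_layout(config)

    total_plant_bases = 0
    for plant in config.motif_plants:
        w = _motif_model(plant.motif).width
        if plant.pair_with is not None:
            w += _motif_model(plant.pair_with).width + 600  # generous spacing allowance
        total_plant_bases += plant.count * (w + 2 * _Packer.GAP)
    if total_plant_bases > config.genome_length // 2:
        raise ValueError(
            f"infeasible packing: {total_plant_bases} plant bases for a "
            f"{config.genome_length} bp genome"
        )

    arrays = {c: _random_bases(rng, n, config.gc_fraction) for c, n in sizes.items()}
    truth = TruthRecord()
    packer = _Packer(sizes, rng)

    def _write(chrom: str, start: int, instance: str, strand: str) -> None:
        seq = instance if strand == "+" else reverse_complement(instance)
        arrays[chrom][start : start + len(seq)] = np.frombuffer(seq.encode(), dtype=np.uint8)

    for plant in config.motif_plants:
        model_a = _motif_model(plant.motif)
        if plant.pair_with is None:
            for _ in range(plant.count):
                strand = "+" if rng.random() < 0.5 else "-"
                chrom, start = packer.place(model_a.width)
                _write(chrom, start, _concrete_instance(rng, model_a.iupac), strand)
                truth.planted_motif_positions.append((chrom, start, strand, plant.motif))
        else:
            model_b = _motif_model(plant.pair_with)
            for _ in range(plant.count):
                if isinstance(plant.spacing, (int, np.integer)):
                    spacing = int(plant.spacing)
                else:
                    mean, sd = plant.spacing
                    spacing = max(model_a.width, int(round(rng.normal(mean, sd))))
                footprint = spacing + model_b.width
                chrom, start = packer.place(footprint)
                _write(chrom, start, _concrete_instance(rng, model_a.iupac), "+")
                b_start = start + spacing
                _write(chrom, b_start, _concrete_instance(rng, model_b.iupac), "+")
                truth.planted_motif_positions.append((chrom, start, "+", plant.motif))
                truth.planted_motif_positions.append((chrom, b_start, "+", plant.pair_with))
                truth.planted_pair_spacing.append(spacing)

    _scrub_background(arrays, truth, config, rng)
    genome = {c: arr.tobytes().decode("ascii") for c, arr in arrays.items()}
    return genome, truth


def _scrub_background(
    arrays: dict[str, np.ndarray],
    truth: TruthRecord,
    config: SynthConfig,
    rng: np.random.Generator,
) -> None:
    """Redraw background windows that exactly match a planted consensus."""
    motif_names = {p.motif for p in config.motif_plants}
    motif_names |= {p.pair_with for p in config.motif_plants if p.pair_with}
    if not motif_names:
        return
    planted = {
        (chrom, start, strand, motif)
        for chrom, start, strand, motif in truth.planted_motif_positions
    }
    protected: dict[str, np.ndarray] = {
        c: np.zeros(arr.size, dtype=bool) for c, arr in arrays.items()
    }
    for chrom, start, _, motif in truth.planted_motif_positions:
        protected[chrom][start : start + _motif_model(motif).width] = True

    for _ in range(60):
        redraw_any = False
        for chrom, arr in arrays.items():
            seq = arr.tobytes().decode("ascii")
            for name in motif_names:
                model = _motif_model(name)
                for hit in scan(seq, model, chrom=chrom):
                    if (chrom, hit.start, hit.strand, name) in planted:
                        continue
                    window = np.arange(hit.start, hit.start + model.width)
                    free = window[~protected[chrom][window]]
                    if free.size == 0:
                        continue  # artifact entirely inside planted footprints
                    arr[free] = _random_bases(rng, free.size, config.gc_fraction)
                    redraw_any = True
        if not redraw_any:
            return
    logger.warning("background scrub did not fully converge after 60 passes")


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def genome_sizes(genome: dict[str, str]) -> dict[str, int]:
    return {c: len(s) for c, s in genome.items()}


# ---------------------------------------------------------------------------
# Peak sets


def make_peak_sets(
    config: SynthConfig, truth: TruthRecord, stream: int = _STREAM_PEAKS
) -> tuple[PeakSet, PeakSet, TruthRecord]:
    """Two peak sets with a controlled pairwise overlap fraction.

    A fraction ``f`` of A-peaks receives a B-peak overlapping it by >= 1 bp;
    remaining B-peaks are placed disjoint from every A-peak. Peaks within
    each set are mutually non-overlapping so that consensus-cluster counts
    are interpretable. When ``motif_anchor_fraction`` > 0, that fraction of
    A-peaks is centered on planted motif positions (without replacement).
    ``truth.true_consensus_intervals`` records the merged A∪B span of every
    overlapping pair, computed by direct pairwise comparison.
    Out-of-bounds placements are clipped with a logged warning.
    """
    params = config.peak_params
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))
    sizes = _chrom_layout(config)
    chroms = list(sizes)
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    n = params.n_peaks
    w = params.mean_width

    def _widths(k: int) -> np.ndarray:
        return np.maximum(w // 4, rng.normal(w, w / 8, size=k).round().astype(int))

    clipped = 0

    def _clip(chrom: str, start: int, end: int) -> tuple[int, int]:
        nonlocal clipped
        lo, hi = max(0, start), min(sizes[chrom], end)
        if (lo, hi) != (start, end):
            clipped += 1
        return lo, hi

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def _free(chrom: str, start: int, end: int, margin: int = 1) -> bool:
        slots = occupied[chrom]
        i = bisect_left(slots, (start, end))
        for j in (i - 1, i):
            if 0 <= j < len(slots):
                s, e = slots[j]
                if start - margin < e and s < end + margin:
                    return False
        return True

    def _reserve(chrom: str, start: int, end: int) -> None:
        insort(occupied[chrom], (start, end))

    # anchored A-peaks on planted motifs
    a_peaks: list[GenomicInterval] = []
    n_anchor = int(round(params.motif_anchor_fraction * n))
    anchors = list(truth.planted_motif_positions)
    if n_anchor > len(anchors):
        raise ValueError(
            f"motif_anchor_fraction requires {n_anchor} plants but only {len(anchors)} exist"
        )
    if n_anchor:
        order = rng.permutation(len(anchors))
        placed = 0
        for idx in order:
            if placed == n_anchor:
                break
            chrom, start, _, _ = anchors[int(idx)]
            width = int(_widths(1)[0])
            lo, hi = _clip(chrom, start + 3 - width // 2, start + 3 - width // 2 + width)
            if hi <= lo or not _free(chrom, lo, hi):
                continue  # anchor too close to an already-placed peak
            a_peaks.append(GenomicInterval(chrom, lo, hi, name="A_anchor"))
            _reserve(chrom, lo, hi)
            placed += 1
        if placed < n_anchor:
            raise ValueError(
                f"could only anchor {placed} of {n_anchor} peaks on planted motifs"
            )

    widths = _widths(n - n_anchor)
    for k in range(n - n_anchor):
        width = int(widths[k])
        for _ in range(2000):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            start = int(rng.integers(0, max(1, sizes[chrom] - width)))
            lo, hi = _clip(chrom, start, start + width)
            if hi > lo and _free(chrom, lo, hi):
                a_peaks.append(GenomicInterval(chrom, lo, hi))
                _reserve(chrom, lo, hi)
                break
        else:
            raise ValueError("could not place A peaks without overlap; genome too small")

    a_set = PeakSet(a_peaks, label="assay_a")

    # B peaks: overlap partners for a chosen subset of A, rest disjoint
    n_overlap = int(round(params.overlap_fraction * len(a_peaks)))
    partner_idx = rng.choice(len(a_peaks), size=n_overlap, replace=False)
    b_peaks: list[GenomicInterval] = []
    b_occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def _b_free(chrom: str, start: int, end: int) -> bool:
        slots = b_occupied[chrom]
        i = bisect_left(slots, (start, end))
        for j in (i - 1, i):
            if 0 <= j < len(slots):
                s, e = slots[j]
                if start < e and s < end:
                    return False
        return True

    consensus: list[tuple[str, int, int]] = []
    for idx in sorted(partner_idx.tolist()):
        a_iv = a_peaks[idx]
        width = int(_widths(1)[0])
        for _ in range(2000):
            # shift such that overlap >= 1 bp is guaranteed
            shift = int(rng.integers(-(width - 1), len(a_iv)))
            lo, hi = _clip(a_iv.chrom, a_iv.start + shift, a_iv.start + shift + width)
            if hi <= lo or min(hi, a_iv.end) - max(lo, a_iv.start) < 1:
                continue
            # must not touch other A peaks or other B peaks
            ok = _b_free(a_iv.chrom, lo, hi)
            if ok:
                for other in a_peaks:
                    if other is a_iv or other.chrom != a_iv.chrom:
                        continue
                    if lo < other.end and other.start < hi:
                        ok = False
                        break
            if ok:
                b_peaks.append(GenomicInterval(a_iv.chrom, lo, hi))
                insort(b_occupied[a_iv.chrom], (lo, hi))
                consensus.append(
                    (a_iv.chrom, min(a_iv.start, lo), max(a_iv.end, hi))
                )
                break
        else:
            raise ValueError("could not place overlapping B peak")

    for _ in range(n - n_overlap):
        width = int(_widths(1)[0])
        for _ in range(2000):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            start = int(rng.integers(0, max(1, sizes[chrom] - width)))
            lo, hi = _clip(chrom, start, start + width)
            if hi <= lo or not _b_free(chrom, lo, hi):
                continue
            if not _free(chrom, lo, hi, margin=1):  # disjoint from all A peaks
                continue
            b_peaks.append(GenomicInterval(chrom, lo, hi))
            insort(b_occupied[chrom], (lo, hi))
            break
        else:
            raise ValueError("could not place disjoint B peak")

    if clipped:
        logger.warning("make_peak_sets: clipped %d peaks at chromosome bounds", clipped)

    truth.true_consensus_intervals = sorted(consensus)
    return a_set, PeakSet(b_peaks, label="assay_b"), truth


# ---------------------------------------------------------------------------
# Count tables


class CountTable:
    """A feature × sample count frame plus a sample → group assignment."""

    def __init__(self, frame, groups: dict[str, list[str]]):
        self.frame = frame
        self.groups = groups
        listed = [s for ss in groups.values() for s in ss]
        if sorted(listed) != sorted(frame.columns):
            raise ValueError("group sample lists must exactly cover the table columns")

    def samples(self, group: str) -> list[str]:
        return self.groups[group]

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.insert(0, "feature_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, groups: dict[str, list[str]]) -> "CountTable":
        df = pd.read_csv(path, sep="\t").set_index("feature_id")
        return cls(df, groups)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float, size) -> np.ndarray:
    """NB with Var = mu + dispersion * mu^2 (shape r = 1/dispersion)."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def make_count_table(config: SynthConfig, stream: int = _STREAM_COUNTS) -> tuple[CountTable, TruthRecord]:
    """Negative-binomial count table with planted differential features.

    The group layout follows ``config.count_params.design``:

    * ``two_group``: ``case`` vs ``control``; a planted fraction of
      features carries the configured log2FC in ``case`` (signs split
      evenly up/down).
    * ``binding``: ``empty`` / ``WT`` / ``C88A``; planted features differ
      WT-vs-empty, and the planted binding-dependent subset reverts to the
      empty-vector mean in C88A (so only that subset differs WT-vs-C88A).
    * ``interactome``: ``control`` / ``WT_N`` / ``WT_C`` / ``C88A``
      spectral counts; planted interactors are elevated in all fusion
      constructs, except the binding-dependent subset which stays at
      control level in C88A.

    Per-feature baselines are log-normal around ``nb_mean`` so the table is
    not artificially homogeneous; the planted effect multiplies the
    baseline, so the group-mean ratio of a planted feature is ``2**log2fc``
    regardless of its baseline.
    """
    params = config.count_params
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))
    nf, ns = params.n_features, params.n_samples
    features = [f"feat{i:05d}" for i in range(nf)]
    baseline = params.nb_mean * np.exp(rng.normal(0, 0.4, size=nf) - 0.08)

    n_planted = int(round(params.planted_fraction * nf))
    planted_idx = rng.choice(nf, size=n_planted, replace=False) if n_planted else np.array([], dtype=int)
    signs = np.ones(n_planted, dtype=int)
    signs[1::2] = -1
    effect = np.ones(nf)
    for idx, s in zip(planted_idx, signs):
        effect[idx] = 2.0 ** (s * params.effect_log2fc)

    truth = TruthRecord()
    if params.effect_log2fc != 0:
        truth.true_differential_features = [
            (features[int(i)], int(s), float(s * params.effect_log2fc))
            for i, s in zip(planted_idx, signs)
        ]

    n_bind = int(round(params.binding_fraction * n_planted))
    bind_idx = set(planted_idx[:n_bind].tolist())

    def _draw(group_means: dict[str, np.ndarray], reps: dict[str, int]) -> CountTable:
        cols, names, groups = [], [], {}
        for group, mu in group_means.items():
            groups[group] = []
            for r in range(reps[group]):
                name = f"{group}_{r + 1}"
                cols.append(_nb_draw(rng, mu, params.nb_dispersion, size=nf))
                names.append(name)
                groups[group].append(name)
        frame = pd.DataFrame(
            np.column_stack(cols) if cols else np.empty((nf, 0)), index=features, columns=names
        )
        frame.index.name = "feature_id"
        return CountTable(frame, groups)

    if params.design == "two_group":
        table = _draw(
            {"case": baseline * effect, "control": baseline},
            {"case": ns, "control": ns},
        )
    elif params.design == "binding":
        wt = baseline * effect
        c88a = baseline.copy() * effect  # non-binding-dependent effects persist
        for idx in bind_idx:
            c88a[idx] = baseline[idx]  # binding-dependent effect ablated
        table = _draw(
            {"empty": baseline, "WT": wt, "C88A": c88a},
            {"empty": ns, "WT": ns, "C88A": ns},
        )
        if params.effect_log2fc != 0:
            truth.true_binding_dependent_features = [
                features[int(i)] for i in planted_idx[:n_bind]
            ]
    else:  # interactome
        wt = baseline * effect
        c88a = baseline * effect
        for idx in bind_idx:
            c88a[idx] = baseline[idx]
        table = _draw(
            {"control": baseline, "WT_N": wt, "WT_C": wt, "C88A": c88a},
            {"control": ns, "WT_N": ns, "WT_C": ns, "C88A": ns},
        )
        if params.effect_log2fc != 0:
            up = [(features[int(i)], int(s)) for i, s in zip(planted_idx, signs) if s > 0]
            truth.true_interactors = [f for f, _ in up]
            truth.true_binding_dependent_interactors = [
                features[int(i)]
                for i, s in zip(planted_idx, signs)
                if s > 0 and int(i) in bind_idx
            ]
    truth.validate()
    return table, truth
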