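"""Configuration, orchestration, and reporting.

``run_pipeline`` executes the full analysis in dependency order:

1. **synth** — generate (or accept) a genome, dual-assay binding peak
   sets, per-genotype accessibility peak sets, a gene annotation, and the
   count tables (expression with a binding-dead contrast, accessibility,
   spectral counts);
2. **consensus** — orthogonally validated binding sites from the two
   assays;
3. **motifs** — motif content of the consensus sites and genome-wide
   heterotypic spacing;
4. **accessibility** — shared / genotype-specific peak partition and
   five-way differential accessibility classes;
5. **enrich** — permutation tests (binding-site enrichment in accessible
   chromatin; motif-pair spacing vs chance);
6. **expression** — DEG classes, binding dependence, direct-target calls,
   and the proximity × direction association;
7. **interactome** — proximity-labeling interactor calls and their
   binding-dependent subset;
8. **report** — a machine-readable JSON summary with per-stage counts,
   planted-truth recovery metrics, parameters and seeds.

Stages communicate only through written files, so a run can be restarted
at any stage; outputs are written atomically and the summary is
byte-identical across reruns with the same config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .integrate import (
    Thresholds,
    accessibility_classes,
    binding_accessibility_report,
    binding_dependence,
    call_direct_targets,
    classify_deg,
    interactome_classify,
    proximity_expression_association,
)
from .intervals import (
    FeatureClassScheme,
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
    intersect_consensus,
    read_bed,
    read_chrom_sizes,
    shared_and_specific,
    write_bed,
)
from .motifscan import BUILTIN_MOTIFS, GATA, RARE_HALF, scan
from .permstats import differential_count_test, region_enrichment_perm, spacing_perm
from .synthgen import (
    CountParams,
    CountTable,
    MotifPlant,
    PeakParams,
    SynthConfig,
    TruthRecord,
    genome_sizes,
    make_count_table,
    make_genome,
    make_peak_sets,
    read_fasta,
    write_fasta,
)

logger = logging.getLogger("bindweave")

# RNG stream offsets for pipeline-level artifacts (see synthgen for 0-2)
_STREAM_ANNOTATION = 3
_STREAM_ATAC_PEAKS = 4
_STREAM_ATAC_COUNTS = 5
_STREAM_A_ONLY = 6
_STREAM_B_ONLY = 7
_STREAM_INTERACTOME = 8
_STREAM_ATAC_COVER = 9


@dataclass
class RunConfig:
    """Everything a pipeline run needs: output directory, thresholds,
    permutation settings, and either a synthetic-generation block or paths
    to user-supplied inputs."""

    outdir: str = "bindweave_run"
    seed: int = 0
    n_perm: int = 199
    thresholds: Thresholds = field(default_factory=Thresholds)
    scheme: FeatureClassScheme = field(default_factory=FeatureClassScheme)
    synthetic: Optional[SynthConfig] = None
    atac_overlap_fraction: float = 0.8
    atac_effect_log2fc: float = float(np.log2(3.0))  # 2x the FC-1.5 threshold
    atac_planted_fraction: float = 0.1
    atac_nb_mean: float = 200.0  # bulk ATAC fragment counts per region
    atac_dispersion: float = 0.02  # bulk-replicate biological CV ~0.14
    atac_cover_fraction: float = 0.9  # consensus sites lying in open chromatin
    specific_planted_fraction: float = 0.3
    interactome: CountParams = field(
        default_factory=lambda: CountParams(
            n_features=800, n_samples=4, nb_mean=30.0, nb_dispersion=0.1,
            effect_log2fc=2.0, planted_fraction=0.1, binding_fraction=0.5,
            design="interactome",
        )
    )
    gene_length: int = 300
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = Thresholds(**kwargs["thresholds"])
        if "scheme" in kwargs:
            kwargs["scheme"] = FeatureClassScheme(**kwargs["scheme"])
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            kwargs["synthetic"] = SynthConfig.from_dict(kwargs["synthetic"])
        if "interactome" in kwargs:
            kwargs["interactome"] = CountParams(**kwargs["interactome"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def demo_config(outdir: str | Path, seed: int = 0, n_perm: int = 199) -> RunConfig:
    """The shipped synthetic end-to-end configuration.

    Scaled to desk size (a few-megabase genome, hundreds of peaks,
    thousands of count features) with planted effects at twice each
    classification threshold, so every downstream class has a recoverable
    planted truth.
    """
    synth = SynthConfig(
        genome_length=3_000_000,
        chrom_count=3,
        gc_fraction=0.41,
        motif_plants=[
            MotifPlant(motif="RARE_half", count=400, pair_with="GATA", spacing=(85.0, 20.0)),
            MotifPlant(motif="RARE_half", count=200),
            MotifPlant(motif="GATA", count=200),
        ],
        peak_params=PeakParams(
            n_peaks=400, mean_width=250, overlap_fraction=0.5, motif_anchor_fraction=0.4
        ),
        count_params=CountParams(
            n_features=2000, n_samples=4, nb_mean=100.0, nb_dispersion=0.1,
            effect_log2fc=2.0, planted_fraction=0.1, binding_fraction=0.5,
            design="binding",
        ),
        seed=seed,
    )
    return RunConfig(outdir=str(outdir), seed=seed, n_perm=n_perm, synthetic=synth)


def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Synthetic input generation


def _make_gene_annotation(
    config: RunConfig,
    synth: SynthConfig,
    consensus: PeakSet,
    truth: TruthRecord,
    sizes: dict[str, int],
) -> tuple[GeneAnnotation, list[str]]:
    """Place one gene per expression feature; a coin-flip half of the
    planted binding-dependent genes are anchored within the proximity
    window of a consensus site (these are the true direct targets), all
    other genes are kept well beyond the window."""
    rng = np.random.default_rng(np.random.SeedSequence(synth.seed, spawn_key=(_STREAM_ANNOTATION,)))
    prox = config.thresholds.proximity
    glen = config.gene_length
    features = [f"feat{i:05d}" for i in range(synth.count_params.n_features)]
    bd = set(truth.true_binding_dependent_features)
    sites = list(consensus)
    chroms = list(sizes)
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    site_arr = {
        c: (
            np.array([s.start for s in sites if s.chrom == c], dtype=np.int64),
            np.array([s.end for s in sites if s.chrom == c], dtype=np.int64),
        )
        for c in chroms
    }

    def _gap_to_sites(chrom: str, start: int, end: int) -> int:
        s, e = site_arr[chrom]
        if s.size == 0:
            return np.iinfo(np.int64).max
        gap = np.maximum(0, np.maximum(s - end, start - e))
        return int(gap.min())

    records = []
    direct_truth: list[str] = []
    for gene in features:
        anchored = gene in bd and sites and rng.random() < 0.5
        if anchored:
            site = sites[int(rng.integers(0, len(sites)))]
            offset = int(rng.integers(0, max(1, prox - 300)))
            start = site.end + offset
            if start + glen > sizes[site.chrom]:
                start = max(0, site.start - offset - glen)
            chrom = site.chrom
            direct_truth.append(gene)
        else:
            for _ in range(500):
                chrom = chroms[int(rng.choice(len(chroms), p=weights))]
                start = int(rng.integers(0, max(1, sizes[chrom] - glen)))
                if _gap_to_sites(chrom, start, start + glen) > prox + 200:
                    break
            else:
                raise StageError("synth", "could not place genes clear of binding sites")
        strand = "+" if rng.random() < 0.5 else "-"
        end = start + glen
        tss = start if strand == "+" else end
        records.append((gene, chrom, strand, start, end, tss))
    return GeneAnnotation.from_records(records), direct_truth


def _recovery(called: set, truth: set) -> dict[str, float]:
    tp = len(called & truth)
    sens = tp / len(truth) if truth else float("nan")
    fdr = (len(called) - tp) / len(called) if called else 0.0
    return {"n_called": len(called), "n_true": len(truth), "sensitivity": sens, "fdr": fdr}


# ---------------------------------------------------------------------------
# Validation


def validate_inputs(config: RunConfig) -> dict:
    """Format and namespace checks over the configured input files.

    Purely diagnostic: returns ``{"passed": bool, "issues": [...],
    "checked": [...]}`` and raises nothing for bad data files themselves.
    """
    issues: list[str] = []
    checked: list[str] = []
    inputs = config.inputs
    if config.synthetic is None and not inputs:
        issues.append("no synthetic block and no input paths configured")

    for key in sorted(inputs):
        path = Path(inputs[key])
        if not path.exists():
            issues.append(f"{key}: missing file {path}")

    chrom_namespaces: dict[str, set[str]] = {}
    for key in ("peaks_a", "peaks_b", "atac_a", "atac_b"):
        if key in inputs and Path(inputs[key]).exists():
            checked.append(key)
            try:
                ps = read_bed(inputs[key])
                chrom_namespaces[key] = set(ps.chroms())
            except ValueError as exc:
                issues.append(f"{key}: {exc}")
    if "genome_fasta" in inputs and Path(inputs["genome_fasta"]).exists():
        checked.append("genome_fasta")
        genome = read_fasta(inputs["genome_fasta"])
        chrom_namespaces["genome_fasta"] = set(genome)
    if "genes" in inputs and Path(inputs["genes"]).exists():
        checked.append("genes")
        try:
            ann = GeneAnnotation.read_tsv(inputs["genes"])
            chrom_namespaces["genes"] = set(ann.chroms())
        except ValueError as exc:
            issues.append(f"genes: {exc}")
    if len(chrom_namespaces) > 1:
        union = set.union(*chrom_namespaces.values())
        for key, chroms in chrom_namespaces.items():
            others = set.union(*(v for k, v in chrom_namespaces.items() if k != key))
            if chroms and others and not (chroms & others):
                issues.append(
                    f"{key}: chromosome namespace {sorted(chroms)[:3]} shares nothing "
                    f"with the other inputs {sorted(others)[:3]}"
                )
    for key in ("expr_counts", "interactome_counts"):
        if key in inputs and Path(inputs[key]).exists():
            checked.append(key)
            header = Path(inputs[key]).read_text().splitlines()[0].split("\t")
            if header[0] != "feature_id":
                issues.append(f"{key}: first header column must be 'feature_id'")
            dupes = {h for h in header if header.count(h) > 1}
            if dupes:
                issues.append(f"{key}: duplicated sample columns {sorted(dupes)}")
    return {"passed": not issues, "issues": issues, "checked": checked}


# ---------------------------------------------------------------------------
# The pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return (and write) the JSON-able run summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.synthetic is None:
        raise StageError("synth", "user-data mode requires a synthetic block or full inputs; "
                         "run individual stages via the CLI for user data")
    synth = config.synthetic
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "thresholds": dataclasses.asdict(config.thresholds),
        "stages": {},
    }

    # --- stage: synth -----------------------------------------------------
    try:
        genome, truth = make_genome(synth)
        peaks_a, peaks_b, truth = make_peak_sets(synth, truth)
        expr_table, expr_truth = make_count_table(synth)
        truth.true_differential_features = expr_truth.true_differential_features
        truth.true_binding_dependent_features = expr_truth.true_binding_dependent_features

        atac_cfg = dataclasses.replace(
            synth,
            peak_params=PeakParams(
                n_peaks=synth.peak_params.n_peaks,
                mean_width=synth.peak_params.mean_width,
                overlap_fraction=config.atac_overlap_fraction,
                motif_anchor_fraction=0.0,
            ),
        )
        atac_a, atac_b, _ = make_peak_sets(atac_cfg, TruthRecord(), stream=_STREAM_ATAC_PEAKS)

        # open chromatin covers most true binding sites (in both genotypes)
        cover_rng = np.random.default_rng(
            np.random.SeedSequence(synth.seed, spawn_key=(_STREAM_ATAC_COVER,))
        )
        sizes = genome_sizes(genome)
        cover = []
        for chrom, start, end in truth.true_consensus_intervals:
            if cover_rng.random() < config.atac_cover_fraction:
                lo = max(0, start - 100)
                hi = min(sizes[chrom], end + 100)
                cover.append(GenomicInterval(chrom, lo, hi, name="open"))
        atac_a = PeakSet(list(atac_a) + cover, label=atac_a.label).merge()
        atac_b = PeakSet(list(atac_b) + cover, label=atac_b.label).merge()

        write_fasta(genome, outdir / "genome.fa")
        _atomic_write_text(
            outdir / "chrom.sizes", "".join(f"{c}\t{n}\n" for c, n in sizes.items())
        )
        write_bed(peaks_a, outdir / "peaks_a.bed")
        write_bed(peaks_b, outdir / "peaks_b.bed")
        write_bed(atac_a, outdir / "atac_a.bed")
        write_bed(atac_b, outdir / "atac_b.bed")
        expr_table.to_tsv(outdir / "expr_counts.tsv")
        summary["stages"]["synth"] = {
            "genome_bp": sum(sizes.values()),
            "chromosomes": len(sizes),
            "n_peaks_a": len(peaks_a),
            "n_peaks_b": len(peaks_b),
            "n_planted_motifs": len(truth.planted_motif_positions),
            "n_planted_pairs": len(truth.planted_pair_spacing),
        }
    except ValueError as exc:
        raise StageError("synth", str(exc)) from exc

    # --- stage: consensus -------------------------------------------------
    peaks_a = read_bed(outdir / "peaks_a.bed", label="assay_a")
    peaks_b = read_bed(outdir / "peaks_b.bed", label="assay_b")
    consensus = intersect_consensus(peaks_a, peaks_b)
    write_bed(consensus, outdir / "consensus_sites.bed")
    summary["stages"]["consensus"] = {
        "n_assay_a": len(peaks_a),
        "n_assay_b": len(peaks_b),
        "n_consensus": len(consensus),
        "n_true_consensus": len(truth.true_consensus_intervals),
    }

    # --- stage: motifs ----------------------------------------------------
    genome = read_fasta(outdir / "genome.fa")
    sizes = read_chrom_sizes(outdir / "chrom.sizes")
    consensus = read_bed(outdir / "consensus_sites.bed", label="consensus")
    rare_hits, gata_hits = [], []
    for chrom, seq in genome.items():
        rare_hits.extend(scan(seq, RARE_HALF, chrom=chrom))
        gata_hits.extend(scan(seq, GATA, chrom=chrom))
    from .motifscan import heterotypic_spacing, peak_motif_fraction, scan_dr5

    frac_rare, _ = peak_motif_fraction(consensus, genome, RARE_HALF)
    frac_gata, _ = peak_motif_fraction(consensus, genome, GATA)
    frac_dr5, _ = peak_motif_fraction(consensus, genome, "DR5")
    spacing = heterotypic_spacing(rare_hits, gata_hits)
    summary["stages"]["motifs"] = {
        "n_rare_half_hits": len(rare_hits),
        "n_gata_hits": len(gata_hits),
        "fraction_sites_with_rare_half": frac_rare,
        "fraction_sites_with_gata": frac_gata,
        "fraction_sites_with_dr5": frac_dr5,
        "mean_rare_gata_spacing_bp": spacing.mean_spacing,
        "planted_pair_mean_spacing_bp": (
            float(np.mean(truth.planted_pair_spacing)) if truth.planted_pair_spacing else None
        ),
    }

    # --- stage: accessibility --------------------------------------------
    atac_a = read_bed(outdir / "atac_a.bed", label="genotype_a")
    atac_b = read_bed(outdir / "atac_b.bed", label="genotype_b")
    shared, a_only, b_only = shared_and_specific(atac_a, atac_b)
    write_bed(shared, outdir / "atac_shared.bed")

    def _region_counts(
        n_features: int, planted: float, stream: int, prefix: str
    ) -> tuple[CountTable, TruthRecord]:
        cfg = dataclasses.replace(
            synth,
            count_params=CountParams(
                n_features=n_features,
                n_samples=synth.count_params.n_samples,
                nb_mean=config.atac_nb_mean,
                nb_dispersion=config.atac_dispersion,
                effect_log2fc=config.atac_effect_log2fc,
                planted_fraction=planted,
                binding_fraction=0.0,
                design="two_group",
            ),
        )
        table, tr = make_count_table(cfg, stream=stream)
        rename = {f: f.replace("feat", prefix) for f in table.frame.index}
        table.frame.index = [rename[f] for f in table.frame.index]
        table.frame.index.name = "feature_id"
        tr.true_differential_features = [
            (rename[f], s, l) for f, s, l in tr.true_differential_features
        ]
        return table, tr

    shared_counts, shared_truth = _region_counts(
        len(shared), config.atac_planted_fraction, _STREAM_ATAC_COUNTS, "region"
    )
    a_counts, a_truth = _region_counts(
        len(a_only), config.specific_planted_fraction, _STREAM_A_ONLY, "aonly"
    )
    b_counts, b_truth = _region_counts(
        len(b_only), config.specific_planted_fraction, _STREAM_B_ONLY, "bonly"
    )
    shared_counts.to_tsv(outdir / "atac_shared_counts.tsv")

    shared_diff = differential_count_test(
        shared_counts.frame, shared_counts.samples("case"), shared_counts.samples("control")
    )
    a_diff = differential_count_test(a_counts.frame, a_counts.samples("case"), a_counts.samples("control"))
    b_diff = differential_count_test(b_counts.frame, b_counts.samples("case"), b_counts.samples("control"))
    classes = accessibility_classes(shared_diff, a_diff, b_diff, config.thresholds)

    region_of = dict(zip(shared_counts.frame.index, shared.intervals))
    increased_ps = PeakSet([region_of[r] for r in classes["increased"]], label="increased")
    decreased_ps = PeakSet([region_of[r] for r in classes["decreased"]], label="decreased")
    write_bed(increased_ps, outdir / "atac_increased.bed")
    write_bed(decreased_ps, outdir / "atac_decreased.bed")

    overlap_report = binding_accessibility_report(consensus, shared, increased_ps, decreased_ps)
    shared_up_truth = {f for f, s, _ in shared_truth.true_differential_features if s > 0}
    shared_down_truth = {f for f, s, _ in shared_truth.true_differential_features if s < 0}
    summary["stages"]["accessibility"] = {
        "n_shared": len(shared),
        "n_a_only": len(a_only),
        "n_b_only": len(b_only),
        "class_counts": {k: len(v) for k, v in classes.items()},
        "binding_overlap": overlap_report,
        "recovery": {
            "increased": _recovery(set(classes["increased"]), shared_up_truth),
            "decreased": _recovery(set(classes["decreased"]), shared_down_truth),
            "a_specific": _recovery(
                set(classes["a_specific"]), {f for f, _, _ in a_truth.true_differential_features}
            ),
            "b_specific": _recovery(
                set(classes["b_specific"]), {f for f, _, _ in b_truth.true_differential_features}
            ),
        },
    }

    # --- stage: enrich ----------------------------------------------------
    enrich = region_enrichment_perm(
        consensus, shared, sizes, n_perm=config.n_perm, seed=config.seed
    )
    spacing_test = spacing_perm(
        rare_hits, gata_hits, sizes, n_perm=config.n_perm, seed=config.seed
    )
    enrich.to_json(outdir / "enrichment_perm.json")
    spacing_test.to_json(outdir / "spacing_perm.json")
    summary["stages"]["enrich"] = {
        "binding_in_accessible": {
            "observed": enrich.observed_statistic,
            "null_mean": float(np.mean(enrich.null_samples)),
            "p": enrich.empirical_p,
        },
        "rare_gata_spacing": {
            "observed_mean_bp": spacing_test.observed_statistic,
            "null_mean_bp": float(np.mean(spacing_test.null_samples)),
            "p": spacing_test.empirical_p,
        },
    }

    # --- stage: expression ------------------------------------------------
    expr = CountTable.read_tsv(
        outdir / "expr_counts.tsv",
        groups={
            g: [f"{g}_{i + 1}" for i in range(synth.count_params.n_samples)]
            for g in ("empty", "WT", "C88A")
        },
    )
    ann, direct_truth = _make_gene_annotation(config, synth, consensus, truth, sizes)
    ann.write_tsv(outdir / "genes.tsv")
    ann = GeneAnnotation.read_tsv(outdir / "genes.tsv")

    wt_vs_empty = classify_deg(
        differential_count_test(expr.frame, expr.samples("WT"), expr.samples("empty")),
        config.thresholds,
    )
    wt_vs_c88a = classify_deg(
        differential_count_test(expr.frame, expr.samples("WT"), expr.samples("C88A")),
        config.thresholds,
    )
    bd = binding_dependence(wt_vs_empty, wt_vs_c88a, config.thresholds)
    targets = call_direct_targets(wt_vs_empty, bd, consensus, ann, config.thresholds)
    targets.to_csv(outdir / "target_calls.tsv", sep="\t")
    association = proximity_expression_association(targets)

    deg_up = set(targets.index[targets["deg_class"] == "up"])
    deg_down = set(targets.index[targets["deg_class"] == "down"])
    truth_up = {f for f, s, _ in truth.true_differential_features if s > 0}
    truth_down = {f for f, s, _ in truth.true_differential_features if s < 0}
    called_bd = set(targets.index[targets["binding_dependent"]])
    called_direct = set(targets.index[targets["direct_target"]])
    summary["stages"]["expression"] = {
        "n_deg": len(deg_up) + len(deg_down),
        "n_up": len(deg_up),
        "n_down": len(deg_down),
        "n_binding_dependent": len(called_bd),
        "n_direct_targets": len(called_direct),
        "direct_up": int((targets["direct_target"] & (targets["deg_class"] == "up")).sum()),
        "direct_down": int((targets["direct_target"] & (targets["deg_class"] == "down")).sum()),
        "proximity_association": {
            d: {"odds_ratio": r["odds_ratio"], "p": r["p"], "table": list(r["table"])}
            for d, r in association.items()
        },
        "recovery": {
            "deg_up": _recovery(deg_up, truth_up),
            "deg_down": _recovery(deg_down, truth_down),
            "binding_dependent": _recovery(called_bd, set(truth.true_binding_dependent_features)),
            "direct_targets": _recovery(called_direct, set(direct_truth)),
        },
    }

    # --- stage: interactome ----------------------------------------------
    inter_cfg = dataclasses.replace(synth, count_params=config.interactome)
    inter_table, inter_truth = make_count_table(inter_cfg, stream=_STREAM_INTERACTOME)
    inter_table.to_tsv(outdir / "interactome_counts.tsv")
    inter_table = CountTable.read_tsv(outdir / "interactome_counts.tsv", groups=inter_table.groups)
    calls = interactome_classify(inter_table.frame, inter_table.groups, config.thresholds)
    calls.to_csv(outdir / "interactome_calls.tsv", sep="\t")
    called_int = set(calls.index[calls["enriched_vs_control"]])
    called_bd_int = set(calls.index[calls["binding_dependent"]])
    summary["stages"]["interactome"] = {
        "n_proteins": len(calls),
        "n_interactors": len(called_int),
        "n_binding_dependent": len(called_bd_int),
        "recovery": {
            "interactors": _recovery(called_int, set(inter_truth.true_interactors)),
            "binding_dependent": _recovery(
                called_bd_int, set(inter_truth.true_binding_dependent_interactors)
            ),
        },
    }

    # --- stage: report ----------------------------------------------------
    truth.to_json(outdir / "truth.json")
    _atomic_write_text(outdir / "run_summary.json", json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", outdir / "run_summary.json")
    return summary
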