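"""Classification rules: DEG classes, binding dependence, direct targets,
accessibility classes, co-occupancy, mediator dependence, interactome
calls, and the indel fold-change summary."""

import numpy as np
import pandas as pd
import pytest

from bindweave.integrate import (
    Thresholds,
    accessibility_classes,
    binding_accessibility_report,
    binding_dependence,
    call_direct_targets,
    classify_deg,
    cooccupancy,
    gata2_dependency,
    indel_fold_change,
    interactome_classify,
    proximity_expression_association,
)
from bindweave.intervals import GeneAnnotation, GenomicInterval, PeakSet
from bindweave.synthgen import CountParams, SynthConfig, make_count_table
from bindweave.permstats import differential_count_test

from conftest import bf_count_overlapping


def _frame(rows):
    """rows: {gene: (log2fc, q)} -> differential frame."""
    idx = list(rows)
    return pd.DataFrame(
        {
            "log2fc": [rows[g][0] for g in idx],
            "p": [rows[g][1] for g in idx],
            "q": [rows[g][1] for g in idx],
        },
        index=idx,
    )


class TestClassifyDeg:
    def test_rule_boundaries(self):
        diff = _frame(
            {
                "up_pass": (1.5, 0.04),     # fc threshold 2 => log2 cut 1.0
                "fdr_fail": (3.0, 0.06),
                "fc_fail": (0.9, 0.01),
                "down_pass": (-1.0, 0.05),  # inclusive comparisons
                "null": (0.0, 1.0),
            }
        )
        out = classify_deg(diff, Thresholds())
        assert out["deg_class"].to_dict() == {
            "up_pass": "up",
            "fdr_fail": "ns",
            "fc_fail": "ns",
            "down_pass": "down",
            "null": "ns",
        }

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(1)
        diff = pd.DataFrame(
            {"log2fc": rng.normal(0, 2, 500), "q": rng.uniform(size=500)},
            index=[f"g{i}" for i in range(500)],
        )
        out = classify_deg(diff, Thresholds())
        assert out["deg_class"].isin(["up", "down", "ns"]).all()
        sig = (out["q"] <= 0.05) & (out["log2fc"].abs() >= 1)
        assert ((out["deg_class"] != "ns") == sig).all()

    def test_missing_q_errors(self):
        with pytest.raises(ValueError, match="'q'"):
            classify_deg(pd.DataFrame({"log2fc": [1.0]}), Thresholds())


class TestBindingDependence:
    def test_same_direction_required(self):
        wt_empty = classify_deg(_frame({"g1": (2, 0.01), "g2": (2, 0.01), "g3": (2, 0.01)}), Thresholds())
        wt_c88a = classify_deg(_frame({"g1": (2, 0.01), "g2": (0.1, 0.9), "g3": (-2, 0.01)}), Thresholds())
        flags = binding_dependence(wt_empty, wt_c88a, Thresholds())
        assert flags.to_dict() == {"g1": True, "g2": False, "g3": False}
        agnostic = binding_dependence(wt_empty, wt_c88a, Thresholds(), require_same_direction=False)
        assert agnostic.to_dict() == {"g1": True, "g2": False, "g3": True}

    def test_mismatched_universe_errors(self):
        a = classify_deg(_frame({"g1": (2, 0.01)}), Thresholds())
        b = classify_deg(_frame({"g2": (2, 0.01)}), Thresholds())
        with pytest.raises(ValueError, match="symmetric difference"):
            binding_dependence(a, b, Thresholds())

    def test_planted_binding_dependence_recovered(self):
        cfg = SynthConfig(
            seed=11,
            count_params=CountParams(n_features=1_500, n_samples=4, nb_mean=100,
                                     nb_dispersion=0.1, effect_log2fc=2.0,
                                     planted_fraction=0.1, binding_fraction=0.5,
                                     design="binding"),
        )
        table, truth = make_count_table(cfg)
        th = Thresholds()
        wt_empty = classify_deg(
            differential_count_test(table.frame, table.samples("WT"), table.samples("empty")), th
        )
        wt_c88a = classify_deg(
            differential_count_test(table.frame, table.samples("WT"), table.samples("C88A")), th
        )
        flags = binding_dependence(wt_empty, wt_c88a, th)
        called = set(flags.index[flags])
        planted = set(truth.true_binding_dependent_features)
        tp = len(called & planted)
        assert tp / len(planted) >= 0.8
        assert (len(called) - tp) / max(1, len(called)) <= 0.10


class TestDirectTargets:
    def _setup(self):
        ann = GeneAnnotation.from_records(
            [
                ("near", "chr1", "+", 2_000, 2_500, 2_000),   # 500 bp from site
                ("far", "chr1", "+", 50_000, 50_500, 50_000),
                ("inside", "chr1", "-", 900, 1_600, 1_600),   # overlaps site
            ]
        )
        sites = PeakSet([GenomicInterval("chr1", 1_000, 1_500)])
        deg = classify_deg(
            _frame({"near": (2, 0.01), "far": (2, 0.01), "inside": (-2, 0.01)}),
            Thresholds(),
        )
        bd = pd.Series({"near": True, "far": True, "inside": False})
        return deg, bd, sites, ann

    def test_direct_requires_proximity_and_dependence(self):
        deg, bd, sites, ann = self._setup()
        out = call_direct_targets(deg, bd, sites, ann, Thresholds())
        assert out.loc["near", "direct_target"]
        assert not out.loc["far", "direct_target"]       # beyond 1 kb
        assert not out.loc["inside", "direct_target"]    # not binding-dependent
        assert out.loc["inside", "distance_to_nearest_site"] == 0
        # invariant: direct => binding-dependent and within window
        direct = out[out["direct_target"]]
        assert direct["binding_dependent"].all()
        assert (direct["distance_to_nearest_site"] <= Thresholds().proximity).all()

    def test_empty_sites_no_direct_targets(self):
        deg, bd, _, ann = self._setup()
        out = call_direct_targets(deg, bd, PeakSet([]), ann, Thresholds())
        assert not out["direct_target"].any()


class TestProximityAssociation:
    def test_extreme_table(self):
        calls = pd.DataFrame(
            {
                "deg_class": ["up"] * 5 + ["ns"] * 10,
                "distance_to_nearest_site": [0.0] * 5 + [np.nan] * 10,
            },
            index=[f"g{i}" for i in range(15)],
        )
        res = proximity_expression_association(calls)
        assert res["up"]["odds_ratio"] == float("inf")
        assert res["up"]["table"] == (5, 0, 0, 10)
        assert res["up"]["p"] == pytest.approx(1 / 3003, rel=1e-9)  # C(15,5) margins

    def test_null_calibration_p_roughly_uniform(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(300):
            calls = pd.DataFrame(
                {
                    "deg_class": rng.choice(["up", "ns"], size=60, p=[0.3, 0.7]),
                    "distance_to_nearest_site": np.where(
                        rng.random(60) < 0.4, 0.0, np.nan
                    ),
                }
            )
            pvals.append(proximity_expression_association(calls)["up"]["p"])
        # Fisher's exact p is conservative; reject at most ~alpha
        assert np.mean(np.array(pvals) <= 0.05) <= 0.07


class TestAccessibilityClasses:
    def test_identical_profiles_all_unchanged(self):
        shared = _frame({f"r{i}": (0.0, 1.0) for i in range(10)})
        empty = pd.DataFrame({"log2fc": []})
        classes = accessibility_classes(shared, empty, empty, Thresholds())
        assert classes["unchanged"] == [f"r{i}" for i in range(10)]
        assert not classes["increased"] and not classes["decreased"]

    def test_five_way_partition(self):
        lfc = np.log2(1.5)
        shared = _frame({"up": (lfc, 0.01), "down": (-lfc, 0.01),
                         "weak": (lfc, 0.5), "flat": (0.0, 0.01)})
        a_only = pd.DataFrame({"log2fc": [lfc, 0.1]}, index=["a1", "a2"])
        b_only = pd.DataFrame({"log2fc": [-lfc]}, index=["b1"])
        classes = accessibility_classes(shared, a_only, b_only, Thresholds())
        assert classes["increased"] == ["up"]
        assert classes["decreased"] == ["down"]
        assert sorted(classes["unchanged"]) == ["flat", "weak"]
        assert classes["a_specific"] == ["a1"]  # fold-change only, no FDR gate
        assert classes["b_specific"] == ["b1"]

    def test_region_in_both_only_lists_errors(self):
        shared = _frame({"r": (0, 1)})
        dup = pd.DataFrame({"log2fc": [1.0]}, index=["x"])
        with pytest.raises(ValueError, match="both"):
            accessibility_classes(shared, dup, dup, Thresholds())


class TestBindingAccessibilityReport:
    def test_sites_subset_of_accessible(self):
        sites = PeakSet([GenomicInterval("chr1", i * 1_000, i * 1_000 + 100) for i in range(5)])
        accessible = PeakSet([GenomicInterval("chr1", 0, 10_000)])
        rep = binding_accessibility_report(sites, accessible)
        assert rep["fraction_accessible"] == 1.0

    def test_random_fractions_match_oracle(self, rng, toy_genome_sizes):
        from conftest import random_peakset

        sites = random_peakset(rng, 150, toy_genome_sizes)
        acc = random_peakset(rng, 150, toy_genome_sizes)
        inc = random_peakset(rng, 50, toy_genome_sizes)
        rep = binding_accessibility_report(sites, acc, increased=inc)
        assert rep["n_overlap_accessible"] == bf_count_overlapping(sites, acc)[0]
        assert rep["n_overlap_increased"] == bf_count_overlapping(sites, inc)[0]


class TestCooccupancy:
    def test_disjoint_sets_no_clusters(self):
        a = PeakSet([GenomicInterval("chr1", 0, 100)])
        b = PeakSet([GenomicInterval("chr1", 500, 600)])
        clusters, summary = cooccupancy(a, b)
        assert len(clusters) == 0 and summary is None

    def test_cluster_count_matches_oracle(self, rng, toy_genome_sizes):
        from conftest import random_peakset, bf_consensus

        a = random_peakset(rng, 200, toy_genome_sizes)
        b = random_peakset(rng, 200, toy_genome_sizes)
        clusters, _ = cooccupancy(a, b)
        assert len(clusters) == len(bf_consensus(a, b))

    def test_spacing_restricted_to_clusters(self):
        from bindweave.motifscan import MotifHit

        a = PeakSet([GenomicInterval("chr1", 0, 300)])
        b = PeakSet([GenomicInterval("chr1", 200, 500)])
        ha = [MotifHit("chr1", 100, "+", "RARE_half"), MotifHit("chr1", 10_000, "+", "RARE_half")]
        hb = [MotifHit("chr1", 185, "+", "GATA")]
        clusters, summary = cooccupancy(a, b, hits_a=ha, hits_b=hb)
        assert summary.distances.tolist() == [85]


class TestMediatorDependency:
    def test_rule_matrix(self):
        primary = classify_deg(
            _frame({"g1": (2, 0.01), "g2": (2, 0.01), "g3": (-2, 0.01), "g4": (0, 1)}),
            Thresholds(),
        )
        oe = classify_deg(
            _frame({"g1": (2, 0.01), "g2": (0, 1), "g3": (-2, 0.01), "g4": (2, 0.01)}),
            Thresholds(),
        )
        ko = classify_deg(
            _frame({"g1": (-2, 0.01), "g2": (0, 1), "g3": (2, 0.01), "g4": (0, 1)}),
            Thresholds(),
        )
        res = gata2_dependency(primary, oe, ko)
        # g1: up in primary, up under OE, down under KO -> coordinate AND dependent
        assert "g1" in res["coordinate"] and "g1" in res["dependent"]
        assert "g2" not in res["coordinate"] and "g2" not in res["dependent"]
        assert "g3" in res["coordinate_down"] and "g3" in res["dependent_down"]
        assert "g4" not in res["coordinate"]

    def test_universe_mismatch_errors(self):
        a = classify_deg(_frame({"g1": (2, 0.01)}), Thresholds())
        b = classify_deg(_frame({"g2": (2, 0.01)}), Thresholds())
        with pytest.raises(ValueError):
            gata2_dependency(a, a, b)


class TestInteractomeClassify:
    def test_flat_protein_not_enriched(self):
        rng = np.random.default_rng(2)
        samples = {g: [f"{g}_{i}" for i in range(1, 4)]
                   for g in ("control", "WT_N", "WT_C", "C88A")}
        data = {s: rng.poisson(30, size=50) for ss in samples.values() for s in ss}
        frame = pd.DataFrame(data, index=[f"p{i}" for i in range(50)])
        calls = interactome_classify(frame, samples, Thresholds())
        assert not calls["enriched_vs_control"].any()
        assert (calls["binding_dependent"] <= calls["enriched_vs_control"]).all()

    def test_missing_construct_errors(self):
        frame = pd.DataFrame({"a": [1, 2]}, index=["p0", "p1"])
        with pytest.raises(ValueError, match="missing construct"):
            interactome_classify(frame, {"control": ["a", "a"]}, Thresholds())

    def test_planted_interactors_recovered(self):
        cfg = SynthConfig(
            seed=21,
            count_params=CountParams(n_features=800, n_samples=4, nb_mean=30,
                                     nb_dispersion=0.1, effect_log2fc=2.0,
                                     planted_fraction=0.1, binding_fraction=0.5,
                                     design="interactome"),
        )
        table, truth = make_count_table(cfg)
        calls = interactome_classify(table.frame, table.groups, Thresholds())
        called = set(calls.index[calls["enriched_vs_control"]])
        called_bd = set(calls.index[calls["binding_dependent"]])
        for got, want in ((called, set(truth.true_interactors)),
                          (called_bd, set(truth.true_binding_dependent_interactors))):
            tp = len(got & want)
            assert tp / len(want) >= 0.8
            assert (len(got) - tp) / max(1, len(got)) <= 0.10
        assert called_bd <= called  # subset chain holds


class TestIndelFoldChange:
    def test_identity(self):
        mi, mf, fc = indel_fold_change([30.0, 40.0], [30.0, 40.0])
        assert fc == 1.0

    def test_reported_precision_two_decimals(self):
        mi, mf, fc = indel_fold_change([56.5], [6.80])
        assert (mi, mf, fc) == (56.5, 6.80, 8.31)

    def test_matches_ratio_of_means_oracle(self):
        rng = np.random.default_rng(3)
        init = rng.uniform(10, 90, 5).tolist()
        fin = rng.uniform(1, 50, 7).tolist()
        _, _, fc = indel_fold_change(init, fin)
        assert fc == round(np.mean(init) / np.mean(fin), 2)

    def test_zero_final_is_inf(self):
        assert indel_fold_change([50.0], [0.0])[2] == float("inf")

    def test_validation(self):
        with pytest.raises(ValueError):
            indel_fold_change([], [1.0])
        with pytest.raises(ValueError):
            indel_fold_change([150.0], [1.0])


def test_thresholds_validation():
    with pytest.raises(ValueError):
        Thresholds(deg_fdr=0)
    with pytest.raises(ValueError):
        Thresholds(deg_fc=1.0)
    with pytest.raises(ValueError):
        Thresholds(proximity=0)
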