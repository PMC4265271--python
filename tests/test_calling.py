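"""Three-step protocol, assignment confidence, filters and null flags."""

import numpy as np
import pandas as pd
import pytest

import polyclust as pc
from polyclust.calling import (
    NC,
    ClusterInfo,
    FilterSpec,
    ProtocolParams,
    assign_samples,
    detect_null_clusters,
    filter_assay,
    label_clusters,
    maf,
)
from polyclust.panel import IntensityPanel
from polyclust.signal_sim import (
    AssayDesign,
    Founder,
    NoiseModel,
    PopulationDesign,
    simulate_panel,
)


def cluster(theta, r=0.9, s=0.02, n=50, null=False):
    return ClusterInfo("C?", theta, r, s, s, n, null=null)


class TestMaf:
    @pytest.mark.parametrize(
        "calls, expected",
        [
            (["AA"] * 10, 0.0),
            (["AA"] * 3 + ["BB"], 0.25),
            (["AA", "AB", "AB", "BB"], 0.5),
            (["AA"] * 3 + ["BB", "NC"], 0.25),  # NC excluded from the denominator
        ],
    )
    def test_biallelic_counts(self, calls, expected):
        assert maf(calls) == pytest.approx(expected)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            calls = list(rng.choice(["AA", "AB", "BB", "NC"], size=30))
            swapped = [
                {"AA": "BB", "BB": "AA"}.get(c, c) for c in calls
            ]
            if all(c == "NC" for c in calls):
                continue
            assert maf(calls) == pytest.approx(maf(swapped))

    def test_cluster_frequency_mode(self):
        calls = ["C1"] * 60 + ["C2"] * 30 + ["C3"] * 10
        value, kind = maf(calls, return_kind=True)
        assert kind == "cluster"
        assert value == pytest.approx(0.1)

    def test_null_calls_excluded_from_allele_frequency(self):
        calls = ["AA"] * 6 + ["BB"] * 2 + ["NULL"] * 10
        assert maf(calls) == pytest.approx(0.25)

    def test_all_nc_is_an_error(self):
        with pytest.raises(ValueError):
            maf(["NC", "NC"])


class TestFilterAssay:
    def test_passing_assay(self):
        calls = ["AA"] * 40 + ["AB"] * 25 + ["BB"] * 30 + ["NC"] * 5
        ok, reasons = filter_assay(calls, FilterSpec((2, 6), 0.90, 0.35), n_clusters=3)
        assert ok and reasons == []

    def test_maf_mode_difference(self):
        calls = ["AA"] * 80 + ["BB"] * 20
        ok_map, reasons = filter_assay(calls, FilterSpec((2, 6), 0.9, 0.35), 2)
        ok_div, _ = filter_assay(calls, FilterSpec((2, 6), 0.9, 0.05), 2)
        assert not ok_map and reasons == ["maf"]
        assert ok_div

    def test_all_reasons_enumerated(self):
        calls = ["AA"] * 50 + ["NC"] * 50
        ok, reasons = filter_assay(calls, FilterSpec((2, 6), 0.9, 0.35), 1)
        assert not ok
        assert reasons == ["cluster_number", "call_rate", "maf"]


class TestLabelClusters:
    def test_three_clusters_get_genotypes(self):
        labelled = label_clusters([cluster(0.95), cluster(0.05), cluster(0.48)])
        assert [c.ordinal for c in labelled] == ["C1", "C2", "C3"]
        assert [c.genotype for c in labelled] == ["AA", "AB", "BB"]

    def test_four_clusters_stay_ordinal(self):
        labelled = label_clusters([cluster(t) for t in (0.8, 0.1, 0.4, 0.6)])
        assert [c.ordinal for c in labelled] == ["C1", "C2", "C3", "C4"]
        assert all(c.genotype is None for c in labelled)

    def test_two_clusters(self):
        labelled = label_clusters([cluster(0.9), cluster(0.1)])
        assert [c.ordinal for c in labelled] == ["C1", "C2"]
        assert all(c.genotype is None for c in labelled)

    def test_null_excluded_from_genotype_labels(self):
        # three genotype clusters plus a null cluster: biallelic interpretation holds
        cl = [cluster(0.05), cluster(0.5), cluster(0.95), cluster(0.4, r=0.05, null=True)]
        labelled = label_clusters(cl)
        genos = {c.ordinal: c.genotype for c in labelled}
        nulls = [c.ordinal for c in labelled if c.null]
        assert sorted(g for g in genos.values() if g) == ["AA", "AB", "BB"]
        assert len(nulls) == 1 and genos[nulls[0]] is None


class TestDetectNull:
    def test_low_intensity_cluster_flagged(self):
        cl = [cluster(0.1, r=1.0), cluster(0.5, r=0.95), cluster(0.8, r=0.08)]
        flagged = detect_null_clusters(cl, r_ratio=0.25)
        assert [c.null for c in flagged] == [False, False, True]

    def test_comparable_intensities_not_flagged(self):
        cl = [cluster(0.1, r=1.0), cluster(0.9, r=0.9)]
        assert not any(c.null for c in detect_null_clusters(cl))

    def test_single_cluster_never_flagged(self):
        cl = [cluster(0.5, r=0.05)]
        assert not any(c.null for c in detect_null_clusters(cl))


class TestAssignSamples:
    def test_point_at_center_called_with_high_confidence(self):
        clusters = [cluster(0.1), cluster(0.9)]  # 40 spreads apart
        call, ordinal, conf = assign_samples(clusters, np.array([0.1]), np.array([0.9]))
        assert conf[0] == pytest.approx(1.0, abs=1e-6)
        assert call[0] != NC

    def test_midpoint_is_half_confidence_and_nc(self):
        clusters = label_clusters([cluster(0.2, s=0.05), cluster(0.6, s=0.05)])
        call, ordinal, conf = assign_samples(clusters, np.array([0.4]), np.array([0.9]))
        assert conf[0] == pytest.approx(0.5, abs=1e-6)
        assert call[0] == NC

    def test_single_cluster_gives_unit_confidence(self):
        clusters = label_clusters([cluster(0.5)])
        call, ordinal, conf = assign_samples(
            clusters, np.array([0.5, 0.52]), np.array([0.9, 0.88])
        )
        assert np.allclose(conf, 1.0)
        assert (call != NC).all()

    def test_far_points_stay_unassigned(self):
        clusters = label_clusters([cluster(0.1), cluster(0.3)])
        call, ordinal, conf = assign_samples(
            clusters, np.array([0.9]), np.array([0.9]), max_std_distance=6.0
        )
        assert call[0] == NC and conf[0] == 0.0

    def test_lower_limit_never_uncalls(self):
        rng = np.random.default_rng(1)
        clusters = label_clusters([cluster(0.2, s=0.05), cluster(0.5, s=0.05)])
        theta = rng.uniform(0.1, 0.6, 200)
        r = np.full(200, 0.9)
        called_at = []
        for limit in (0.95, 0.8, 0.5):
            call, _, _ = assign_samples(clusters, theta, r, confidence_limit=limit)
            called_at.append(int((call != NC).sum()))
        assert called_at == sorted(called_at)


def _panel_from_theta(theta_rows, r_rows, markers):
    n = len(theta_rows[0])
    samples = [f"s{i:03d}" for i in range(n)]
    return IntensityPanel(
        pd.DataFrame(theta_rows, index=markers, columns=samples),
        pd.DataFrame(r_rows, index=markers, columns=samples),
    )


class TestRunProtocol:
    def test_well_separated_assay_accepted_at_step1(self):
        designs = [AssayDesign("m")]
        pops = [PopulationDesign("P", "diversity", 300, allele_freq=0.5, inbreeding=0.5)]
        panel, truth = simulate_panel(designs, pops, NoiseModel(), seed=1)
        model, geno, rep = pc.run_protocol(panel, mode="diversity")
        assert rep.frame.iloc[0]["status"] == "1"
        assert model.is_biallelic("m")
        acc = pc.call_accuracy(geno, truth)
        assert acc.concordance > 0.99

    def test_compressed_assay_split_at_step2(self):
        from polyclust.scenarios import compressed_pair_panel

        panel, truth = compressed_pair_panel(seed=3, n_markers=1, n_samples=100)
        model, geno, rep = pc.run_protocol(panel, mode="mapping")
        assert rep.frame.iloc[0]["status"] == "2"
        assert model.n_clusters(panel.markers[0]) == 2
        acc = pc.call_accuracy(geno, truth)
        assert acc.concordance > 0.95

    def test_broad_assay_recovered_at_step3(self):
        rng = np.random.default_rng(0)
        n = 25
        theta = np.clip(
            np.concatenate([rng.normal(0.27, 0.12, n), rng.normal(0.73, 0.12, n)]),
            0, 1,
        )
        r = rng.lognormal(0, 0.3, 2 * n)
        panel = _panel_from_theta([theta], [r], ["broad"])
        _, _, rep = pc.run_protocol(panel, mode="diversity")
        row = rep.frame.iloc[0]
        assert row["status"] == "3"
        assert "1:fail" in row["history"]

    def test_noiseless_panel_recovers_truth_exactly(self):
        designs = [AssayDesign("m1"), AssayDesign("m2", n_hyb_sites=2, fixed_alleles={1: "A"})]
        pops = [PopulationDesign("P", "diversity", 200, allele_freq=0.5, inbreeding=0.5)]
        panel, truth = simulate_panel(
            designs, pops, NoiseModel(theta_sd=0.0, r_cv=0.0), seed=2
        )
        model, geno, rep = pc.run_protocol(panel, mode="diversity")
        acc = pc.call_accuracy(geno, truth)
        assert acc.concordance == 1.0
        assert acc.nc_rate == 0.0

    def test_every_marker_has_exactly_one_terminal_status(self, small_benchmark):
        panel, _ = small_benchmark
        _, _, rep = pc.run_protocol(panel, mode="diversity")
        assert len(rep.frame) == panel.n_markers
        assert rep.frame["marker"].is_unique
        assert sum(rep.step_counts().values()) == panel.n_markers

    def test_unknown_mode_rejected(self, small_benchmark):
        panel, _ = small_benchmark
        with pytest.raises(ValueError):
            pc.run_protocol(panel, mode="plaid")

    def test_null_cluster_members_are_deletion_carriers(self):
        designs = [AssayDesign("m", failure_sites=(0,), failure_freq=0.3)]
        pops = [PopulationDesign("P", "diversity", 500, allele_freq=0.5, inbreeding=1.0)]
        panel, truth = simulate_panel(designs, pops, NoiseModel(), seed=4)
        model, geno, rep = pc.run_protocol(panel, mode="diversity")
        assert any(c.null for c in model.markers["m"])
        t = truth.marker("m")
        calls = geno.marker_calls("m")
        null_called = calls[calls == "NULL"].index
        true_null = set(t.index[t["null"]])
        agreement = len(set(null_called) & true_null) / max(len(true_null), 1)
        assert agreement >= 0.95

    def test_residual_heterozygotes_keep_their_call(self):
        """DH residual hets land in the AB cluster when one exists."""
        designs = [AssayDesign("m")]
        parents = {"m": (Founder("A"), Founder("B"))}
        pops = [
            PopulationDesign("DH", "DH", 300, het_rate=0.1, parents=parents),
        ]
        panel, truth = simulate_panel(designs, pops, NoiseModel(), seed=5)
        model, geno, _ = pc.run_protocol(panel, mode="mapping")
        t = truth.marker("m")
        hets = t.index[t["genotype"] == "AB"]
        calls = geno.marker_calls("m")[hets]
        assert (calls == "AB").mean() > 0.9


class TestApplyModel:
    def test_reapplication_to_training_panel_is_identical(self, small_benchmark):
        panel, _ = small_benchmark
        model, geno, _ = pc.run_protocol(panel, mode="diversity")
        again = pc.apply_model(model, panel)
        trained = geno.frame[geno.frame["marker"].isin(model.markers)].reset_index(drop=True)
        pd.testing.assert_frame_equal(trained, again.frame)

    def test_novel_cluster_samples_become_nc(self):
        noise = NoiseModel()
        pops = [PopulationDesign("P", "diversity", 300, allele_freq=0.5, inbreeding=0.6)]
        train_panel, _ = simulate_panel([AssayDesign("m")], pops, noise, seed=6)
        model, _, _ = pc.run_protocol(train_panel, mode="diversity")

        # the application panel carries a deletion absent from training
        apply_panel, truth = simulate_panel(
            [AssayDesign("m", failure_sites=(0,), failure_freq=0.4)], pops, noise, seed=7
        )
        geno = pc.apply_model(model, apply_panel)
        t = truth.marker("m")
        null_samples = t.index[t["null"]]
        calls = geno.marker_calls("m")[null_samples]
        assert len(null_samples) > 30
        assert (calls == NC).mean() > 0.95
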