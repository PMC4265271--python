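"""Population summary statistics against hand counts and oracles."""

import numpy as np
import pandas as pd
import pytest

from polyclust.popstats import (
    ld_r2,
    mean_heterozygosity,
    pairwise_fst,
    pairwise_stat_table,
    shared_polymorphic,
    weir_cockerham_fst,
)
from polyclust.scenarios import differentiated_counts

from oracles import wc84_theta_oracle


def wide(rows: dict[str, list[str]]) -> pd.DataFrame:
    n = len(next(iter(rows.values())))
    return pd.DataFrame(rows, index=[f"s{i}" for i in range(n)]).T


def one_pop(calls: pd.DataFrame) -> pd.Series:
    return pd.Series("P", index=calls.columns)


class TestMeanHeterozygosity:
    def test_three_marker_hand_computation(self):
        calls = wide(
            {
                "m1": ["AB"] * 2 + ["AA"] * 8,          # p = 0.1 -> 0.18
                "m2": ["AB"] * 6 + ["AA"] * 4,          # p = 0.3 -> 0.42
                "m3": ["AB"] * 10,                      # p = 0.5 -> 0.50
            }
        )
        h = mean_heterozygosity(calls, one_pop(calls))
        assert h["P"] == pytest.approx((0.18 + 0.42 + 0.5) / 3)

    def test_maximum_diversity(self):
        calls = wide({"m1": ["AA", "BB"] * 5, "m2": ["AA", "BB"] * 5})
        assert mean_heterozygosity(calls, one_pop(calls))["P"] == pytest.approx(0.5)

    def test_monomorphic_population_undefined(self):
        calls = wide({"m1": ["AA"] * 6})
        assert np.isnan(mean_heterozygosity(calls, one_pop(calls))["P"])

    def test_observed_variant(self):
        calls = wide({"m1": ["AB"] * 3 + ["AA"] * 7})
        h = mean_heterozygosity(calls, one_pop(calls), kind="observed")
        assert h["P"] == pytest.approx(0.3)


class TestWeirCockerham:
    def test_fixed_alternative_alleles_give_unity(self):
        c1 = np.array([[0, 0, 10]])
        c2 = np.array([[10, 0, 0]])
        assert weir_cockerham_fst(c1, c2) == 1.0

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(0)
        c = rng.multinomial(40, [0.3, 0.4, 0.3], size=50)
        assert weir_cockerham_fst(c, c) <= 1e-12

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        c1 = rng.multinomial(30, [0.5, 0.3, 0.2], size=30)
        c2 = rng.multinomial(30, [0.2, 0.3, 0.5], size=30)
        assert weir_cockerham_fst(c1, c2) == pytest.approx(
            weir_cockerham_fst(c2, c1), abs=1e-15
        )

    def test_matches_component_transcription(self):
        """Vectorised estimator equals the scalar WC84 transcription."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            m = rng.integers(1, 20)
            c1 = rng.multinomial(rng.integers(5, 60), rng.dirichlet([1, 1, 1]), size=m)
            c2 = rng.multinomial(rng.integers(5, 60), rng.dirichlet([1, 1, 1]), size=m)
            ours = weir_cockerham_fst(c1, c2)
            ref = wc84_theta_oracle(c1, c2)
            if np.isnan(ref):
                assert np.isnan(ours)
            else:
                assert ours == pytest.approx(ref, abs=1e-12)

    def test_single_marker_example(self):
        # 10 samples each, allele counts 18/2 versus 2/18
        c1 = np.array([[0, 2, 8]])
        c2 = np.array([[8, 2, 0]])
        assert weir_cockerham_fst(c1, c2) == pytest.approx(
            wc84_theta_oracle(c1, c2), abs=1e-12
        )

    def test_recovers_generating_differentiation(self):
        """Balding-Nichols frequency draws at F_ST 0.15 are recovered
        within Monte-Carlo error."""
        estimates = [
            weir_cockerham_fst(*differentiated_counts(seed, fst=0.15, n_markers=500))
            for seed in range(10)
        ]
        assert np.mean(estimates) == pytest.approx(0.15, abs=0.02)


class TestLdR2:
    def test_printed_haplotype_table(self):
        # haplotype counts BB=40, Bb=10, bB=10, bb=40 -> D = 0.15, r2 = 0.36
        a = ["BB"] * 40 + ["BB"] * 10 + ["AA"] * 10 + ["AA"] * 40
        b = ["BB"] * 40 + ["AA"] * 10 + ["BB"] * 10 + ["AA"] * 40
        r2, method = ld_r2(pd.Series(a), pd.Series(b), with_method=True)
        assert method == "haplotype"
        assert r2 == pytest.approx(0.36, abs=1e-12)

    def test_complete_linkage(self):
        a = pd.Series(["AA"] * 30 + ["BB"] * 30)
        assert ld_r2(a, a.copy()) == pytest.approx(1.0)

    def test_independent_markers_near_zero(self):
        rng = np.random.default_rng(3)
        a = pd.Series(rng.choice(["AA", "BB"], 1000))
        b = pd.Series(rng.choice(["AA", "BB"], 1000))
        assert ld_r2(a, b) < 0.05

    def test_allele_swap_invariance(self):
        rng = np.random.default_rng(4)
        a = pd.Series(rng.choice(["AA", "AB", "BB"], 200))
        b = pd.Series(rng.choice(["AA", "AB", "BB"], 200))
        swapped = a.map({"AA": "BB", "AB": "AB", "BB": "AA"})
        assert ld_r2(a, b) == pytest.approx(ld_r2(swapped, b), abs=1e-12)

    def test_heterozygotes_force_genotype_correlation(self):
        a = pd.Series(["AA"] * 20 + ["AB"] * 20 + ["BB"] * 20)
        b = pd.Series(["AA"] * 20 + ["AB"] * 20 + ["BB"] * 20)
        r2, method = ld_r2(a, b, with_method=True)
        assert method == "genotype_correlation"
        assert r2 == pytest.approx(1.0)

    def test_monomorphic_marker_undefined(self):
        with pytest.raises(ValueError):
            ld_r2(pd.Series(["AA"] * 10), pd.Series(["AA", "BB"] * 5))


class TestSharedPolymorphic:
    def test_marker_private_to_one_population(self):
        calls = wide(
            {
                "m1": ["AA", "AB", "AA", "AA", "AA", "AA"],  # poly in A only
                "m2": ["AA", "AA", "AA", "AB", "AA", "AA"],  # poly in B only
            }
        )
        part = pd.Series(["A"] * 3 + ["B"] * 3, index=calls.columns)
        shared = shared_polymorphic(calls, part)
        assert shared.loc["A", "B"] == 0

    def test_idempotence_on_identical_partitions(self):
        rng = np.random.default_rng(5)
        calls = wide({f"m{i}": list(rng.choice(["AA", "AB", "BB"], 8)) for i in range(6)})
        part = pd.Series("P", index=calls.columns)
        shared = shared_polymorphic(calls, part)
        # diagonal equals the population's own polymorphic count
        from polyclust.popstats import allele_freq

        p = allele_freq(calls)
        n_poly = int(((p > 0) & (p < 1)).sum())
        assert shared.loc["P", "P"] == n_poly

    def test_toy_table_matches_enumeration(self):
        calls = wide(
            {
                "m1": ["AA", "BB", "AA", "BB", "AA", "BB"],
                "m2": ["AA", "AA", "AA", "AB", "AA", "AA"],
                "m3": ["BB", "BB", "AB", "AA", "AA", "AA"],
                "m4": ["AA", "AA", "AA", "AA", "AA", "AA"],
                "m5": ["AB", "AA", "BB", "BB", "AB", "BB"],
            }
        )
        part = pd.Series(["X", "X", "Y", "Y", "Z", "Z"], index=calls.columns)
        shared = shared_polymorphic(calls, part)
        # brute force over the table
        from polyclust.popstats import allele_freq

        pops = ["X", "Y", "Z"]
        for i, a in enumerate(pops):
            for b in pops[i:]:
                expected = 0
                for m in calls.index:
                    ok = True
                    for pop in {a, b}:
                        sub = calls.loc[[m], part.index[part == pop]]
                        p = allele_freq(sub).iloc[0]
                        ok &= bool(p > 0 and p < 1)
                    expected += int(ok)
                assert shared.loc[a, b] == expected

    def test_combined_table_layout(self):
        rng = np.random.default_rng(6)
        calls = wide({f"m{i}": list(rng.choice(["AA", "AB", "BB"], 30)) for i in range(40)})
        part = pd.Series(["A"] * 15 + ["B"] * 15, index=calls.columns)
        table = pairwise_stat_table(calls, part)
        fst = pairwise_fst(calls, part)
        shared = shared_polymorphic(calls, part)
        assert table.loc["A", "B"] == shared.loc["A", "B"]  # upper: counts
        assert table.loc["B", "A"] == pytest.approx(fst.loc["B", "A"])  # lower: F_ST
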