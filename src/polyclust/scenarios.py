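"""Canonical simulated study conditions used by tests and benchmarks.

These builders freeze the panel compositions the package is validated on,
so that every consumer (unit tests, the acceptance checks, the examples)
measures the same conditions:

``benchmark_panel``
    the default calling benchmark — 1000 samples x 200 assays mixing
    2-, 3- and 4-cluster geometries, cluster compression from a duplicated
    gene copy, and null-allele (deletion) assays, at theta noise 0.02 and
    10% intensity CV.
``compressed_pair_panel``
    doubled-haploid assays whose two homozygous clusters sit ~0.10 apart
    in theta (a 7-copy hybridisation design), the geometry the forced
    two-cluster OPTICS step exists for.
``nontarget_snp_panel``
    assays with a secondary SNP silencing a nontarget gene copy, genotyped
    in two DH populations that segregate between different cluster pairs
    sharing one cluster — the scenario the bi-parental allelic-map
    resolution reconstructs.
``differentiated_counts``
    Balding-Nichols allele-frequency draws for two populations at a chosen
    F_ST, the oracle for the Weir-Cockerham estimator.
"""

from __future__ import annotations

import numpy as np

from .signal_sim import (
    AssayDesign,
    Founder,
    NoiseModel,
    PopulationDesign,
    TruthSet,
    simulate_panel,
)
from .panel import IntensityPanel

__all__ = [
    "benchmark_designs",
    "benchmark_panel",
    "compressed_pair_panel",
    "nontarget_snp_panel",
    "differentiated_counts",
]

#: default measurement noise for all canonical scenarios
DEFAULT_NOISE = NoiseModel(theta_sd=0.02, r_cv=0.1, r_baseline=0.08)


def _subseed(seed: int, label: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), label]))


def benchmark_designs(seed: int, n_assays: int = 200):
    """Assay mix of the default benchmark.

    35% three-cluster single-copy SNPs, 20% two-cluster assays polymorphic
    only in the mapping population, 25% compressed assays (one constitutive
    duplicate copy halves the theta separation), 20% null-allele assays
    segregating a deletion haplotype at frequency 0.3.  Per-marker allele
    frequencies are drawn once from the seed.
    """
    rng = _subseed(seed, 1)
    n_tri = round(0.35 * n_assays)
    n_bi = round(0.20 * n_assays)
    n_comp = round(0.25 * n_assays)
    n_null = n_assays - n_tri - n_bi - n_comp

    designs: list[AssayDesign] = []
    freqs: dict[str, float] = {}
    parents: dict[str, tuple[Founder, Founder]] = {}

    for i in range(n_tri):
        m = f"TRI{i:04d}"
        designs.append(AssayDesign(marker_id=m))
        freqs[m] = float(rng.uniform(0.2, 0.5))
    for i in range(n_bi):
        m = f"BI{i:04d}"
        designs.append(AssayDesign(marker_id=m))
        freqs[m] = 0.0  # monomorphic in the diverse accessions
        parents[m] = (Founder("B"), Founder("A"))  # but segregating in the cross
    for i in range(n_comp):
        m = f"CMP{i:04d}"
        designs.append(
            AssayDesign(marker_id=m, n_hyb_sites=2, target_site_index=0,
                        fixed_alleles={1: "A"})
        )
        freqs[m] = float(rng.uniform(0.3, 0.5))
    for i in range(n_null):
        m = f"NUL{i:04d}"
        designs.append(
            AssayDesign(marker_id=m, failure_sites=(0,), failure_freq=0.3)
        )
        freqs[m] = float(rng.uniform(0.25, 0.5))
    return designs, freqs, parents


def benchmark_panel(
    seed: int,
    n_samples: int = 1000,
    n_assays: int = 200,
    noise: NoiseModel = DEFAULT_NOISE,
) -> tuple[IntensityPanel, TruthSet]:
    """The default calling benchmark: 1000 samples x 200 assays.

    The sample set mirrors a cluster-file training panel: 600 fully inbred
    diverse accessions, a 250-line DH population and 150 partially
    heterozygous F4-type lines that populate the heterozygote clusters.
    """
    designs, freqs, bi_parents = benchmark_designs(seed, n_assays)
    n_div = round(0.6 * n_samples)
    n_dh = round(0.25 * n_samples)
    n_f4 = n_samples - n_div - n_dh
    pops = [
        PopulationDesign("DIV", "diversity", n_div, allele_freq=freqs, inbreeding=1.0),
        PopulationDesign("DH1", "DH", n_dh, allele_freq=freqs, parents=bi_parents),
        PopulationDesign("F4A", "F4", n_f4, allele_freq=freqs),
    ]
    return simulate_panel(designs, pops, noise, seed=seed)


def compressed_pair_panel(
    seed: int,
    n_markers: int = 100,
    n_samples: int = 100,
    noise: NoiseModel = DEFAULT_NOISE,
) -> tuple[IntensityPanel, TruthSet]:
    """Tightly compressed two-cluster DH assays.

    Seven hybridisation sites with six constitutive A copies put the two
    homozygous clusters at theta 0 and (2/pi)·arctan(1/6) ≈ 0.105 — close
    enough that DBSCAN at radius 0.07 usually merges them.  The DH lines
    are fully homozygous (no residual heterozygosity), so the truth is an
    exact two-way split of ~n_samples/2 points per cluster.
    """
    designs = [
        AssayDesign(
            marker_id=f"CPR{i:04d}", n_hyb_sites=7, target_site_index=0,
            fixed_alleles={s: "A" for s in range(1, 7)},
        )
        for i in range(n_markers)
    ]
    parents = {d.marker_id: (Founder("A"), Founder("B")) for d in designs}
    pop = PopulationDesign(
        "DHC", "DH", n_samples, het_rate=0.0, parents=parents
    )
    return simulate_panel(designs, [pop], noise, seed=seed)


def nontarget_snp_panel(
    seed: int,
    n_markers: int = 100,
    n_per_pop: int = 100,
    noise: NoiseModel = DEFAULT_NOISE,
) -> tuple[IntensityPanel, TruthSet]:
    """Two DH populations resolving a three-cluster multi-locus assay.

    Each assay targets a [A/B] SNP on one genome while the probe also
    anneals to a second genome copy contributing a constitutive A allele;
    a secondary SNP silences that copy in carriers.  Population P1 is fixed
    B at the target and segregates for the silencing polymorphism
    (clusters C2 <-> C3); population P2 carries the silenced copy and
    segregates at the target SNP (clusters C1 <-> C3).  C3 — silenced
    copy, B/B at the target — is the cluster the two crosses share.
    """
    designs = [
        AssayDesign(
            marker_id=f"NTS{i:04d}", n_hyb_sites=2, target_site_index=0,
            fixed_alleles={1: "A"}, failure_sites=(1,), failure_freq=0.5,
        )
        for i in range(n_markers)
    ]
    p1 = {
        d.marker_id: (Founder("B"), Founder("B", frozenset({1})))
        for d in designs
    }
    p2 = {
        d.marker_id: (Founder("A", frozenset({1})), Founder("B", frozenset({1})))
        for d in designs
    }
    pops = [
        PopulationDesign("P1", "DH", n_per_pop, het_rate=0.0, parents=p1),
        PopulationDesign("P2", "DH", n_per_pop, het_rate=0.0, parents=p2),
    ]
    return simulate_panel(designs, pops, noise, seed=seed)


def differentiated_counts(
    seed: int,
    fst: float,
    n_markers: int = 2000,
    n_per_pop: int = 100,
    ancestral_freq: tuple[float, float] = (0.1, 0.9),
):
    """Genotype-count tables for two populations at a target F_ST.

    Per marker an ancestral frequency p is drawn uniformly, each
    population's frequency from the Balding-Nichols distribution
    Beta(p(1-F)/F, (1-p)(1-F)/F), and Hardy-Weinberg genotype counts from
    it.  Returns two (n_markers, 3) arrays of (nAA, nAB, nBB) whose
    Weir-Cockerham estimate should recover ``fst`` up to Monte-Carlo error.
    """
    if not 0 < fst < 1:
        raise ValueError("fst must be in (0, 1)")
    rng = _subseed(seed, 99)
    p = rng.uniform(*ancestral_freq, n_markers)
    shape = (1 - fst) / fst
    counts = []
    for _ in range(2):
        pk = rng.beta(p * shape, (1 - p) * shape)
        g = rng.binomial(2, pk[:, None] * np.ones((n_markers, n_per_pop)))
        counts.append(
            np.column_stack([(g == 0).sum(1), (g == 1).sum(1), (g == 2).sum(1)])
        )
    return counts[0], counts[1]
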