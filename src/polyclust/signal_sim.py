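"""Synthetic two-channel intensity data with polyploid dosage geometry.

In an allopolyploid like bread wheat, an array probe designed against one
gene copy usually also hybridises to its homoeologues and paralogues.  Every
hybridising copy contributes constitutive signal, so the observed
fluorescence ratio reflects the *dosage* of the two alleles summed over all
copies, not just the segregating target site.  This produces the cluster
geometries that make polyploid calling hard:

* cluster compression — constitutive signal from nontarget copies shrinks
  the angular (theta) separation between the homozygous classes;
* extra clusters — a secondary polymorphism in a probe annealing site
  silences one gene copy in carriers, shifting both theta and total
  intensity R and adding clusters beyond the three expected for a biallelic
  SNP;
* null clusters — when every hybridising copy is deleted or diverged the
  sample yields only background intensity, a low-R cluster with arbitrary
  theta.

The generator draws genotypes for diversity panels (partially inbred),
doubled-haploid (DH) and partially heterozygous F4-type bi-parental
populations, converts them to channel dosages, applies noise, and emits the
panel together with a :class:`TruthSet` recording the generating
configuration of every point — the oracle all downstream tests compare
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import IntensityPanel

__all__ = [
    "NullSignalError",
    "AssayDesign",
    "Founder",
    "PopulationDesign",
    "NoiseModel",
    "TruthSet",
    "dosage_to_theta",
    "expected_dosage",
    "simulate_panel",
]

#: genotype strings used throughout the package
GENOTYPES = ("AA", "AB", "BB")

#: signal dose contributed per working gene copy (two copies per site per sample)
R_PER_DOSE = 0.5


class NullSignalError(ValueError):
    """Raised when a theta is requested for a zero-signal (null) point."""


def dosage_to_theta(x_dose: float, y_dose: float) -> float:
    """Normalised polar angle of a dosage pair.

    theta = (2/pi) * arctan(y/x): 0 for pure A-channel signal, 1 for pure
    B-channel signal (x = 0).  Raises :class:`NullSignalError` when both
    doses are zero — a null point has no defined angle and must be handled
    by the caller.
    """
    if x_dose < 0 or y_dose < 0:
        raise ValueError("doses must be non-negative")
    if x_dose == 0 and y_dose == 0:
        raise NullSignalError("theta undefined for a zero-signal point")
    return float((2.0 / np.pi) * np.arctan2(y_dose, x_dose))


@dataclass(frozen=True)
class AssayDesign:
    """Hybridisation structure of one assay probe.

    The probe anneals to ``n_hyb_sites`` gene copies.  Exactly one of them
    (``target_site_index``) carries the segregating SNP; every other site
    contributes a constitutively fixed allele given by ``fixed_alleles``
    (mapping site index -> 'A' or 'B').  Sites listed in ``failure_sites``
    segregate for a failure haplotype (gene deletion or probe-site
    divergence) at frequency ``failure_freq``; a failed copy contributes no
    signal.  ``site_weights`` optionally scales the per-copy signal of each
    site (default: equal weight 1.0 per site).
    """

    marker_id: str
    n_hyb_sites: int = 1
    target_site_index: int = 0
    fixed_alleles: Mapping[int, str] = field(default_factory=dict)
    failure_sites: tuple[int, ...] = ()
    failure_freq: float = 0.0
    site_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_hyb_sites < 1:
            raise ValueError("n_hyb_sites must be >= 1")
        if not 0 <= self.target_site_index < self.n_hyb_sites:
            raise ValueError("target_site_index must be < n_hyb_sites")
        nontarget = set(range(self.n_hyb_sites)) - {self.target_site_index}
        if set(self.fixed_alleles) != nontarget:
            raise ValueError(
                "fixed_alleles must cover exactly the nontarget sites "
                f"{sorted(nontarget)}, got {sorted(self.fixed_alleles)}"
            )
        for allele in self.fixed_alleles.values():
            if allele not in ("A", "B"):
                raise ValueError("fixed alleles must be 'A' or 'B'")
        if not set(self.failure_sites) <= set(range(self.n_hyb_sites)):
            raise ValueError("failure_sites outside site range")
        if not 0.0 <= self.failure_freq <= 1.0:
            raise ValueError("failure_freq must be in [0, 1]")
        if self.site_weights is not None and len(self.site_weights) != self.n_hyb_sites:
            raise ValueError("site_weights length must equal n_hyb_sites")

    def weight(self, site: int) -> float:
        return 1.0 if self.site_weights is None else float(self.site_weights[site])


@dataclass(frozen=True)
class Founder:
    """One founder haplotype: target-site allele plus failed-site carriage."""

    allele: str = "A"
    failed_sites: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.allele not in ("A", "B"):
            raise ValueError("founder allele must be 'A' or 'B'")


@dataclass
class PopulationDesign:
    """Sampling scheme for one population.

    kinds
        ``diversity``: unrelated accessions.  Genotypes are drawn per locus
        with allele frequency ``allele_freq`` and inbreeding coefficient
        ``inbreeding`` (wheat accessions are near-fully selfed; heterozygote
        frequency is ``2pq(1 - inbreeding)``).
        ``DH``: doubled-haploid bi-parental progeny — homozygous at every
        locus apart from residual heterozygosity ``het_rate`` (default 0.02),
        each unlinked locus inherited 1:1 from the two parents.
        ``F4``: partially heterozygous bi-parental progeny, heterozygous at
        rate ``het_rate`` (default 0.125, the F4 expectation) where the
        parents differ.

    ``allele_freq`` may be a scalar or a per-marker mapping.  ``parents``
    optionally fixes the founder pair per marker for the bi-parental kinds;
    markers not listed get founders drawn from ``allele_freq`` and the
    design's failure frequency.
    """

    pop_id: str
    kind: str
    n_samples: int
    allele_freq: float | Mapping[str, float] = 0.3
    het_rate: float | None = None
    inbreeding: float = 0.9
    parents: Mapping[str, tuple[Founder, Founder]] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("diversity", "DH", "F4"):
            raise ValueError(f"unknown population kind {self.kind!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.het_rate is None:
            self.het_rate = {"diversity": 0.0, "DH": 0.02, "F4": 0.125}[self.kind]
        if not 0.0 <= float(self.het_rate) <= 1.0:
            raise ValueError("het_rate must be in [0, 1]")
        if not 0.0 <= self.inbreeding <= 1.0:
            raise ValueError("inbreeding must be in [0, 1]")

    def freq(self, marker_id: str) -> float:
        if isinstance(self.allele_freq, Mapping):
            p = float(self.allele_freq[marker_id])
        else:
            p = float(self.allele_freq)
        if not 0.0 <= p <= 1.0:
            raise ValueError("allele frequency must be in [0, 1]")
        return p

    def sample_ids(self) -> list[str]:
        return [f"{self.pop_id}_{i:04d}" for i in range(self.n_samples)]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise applied to the ideal dosage signal.

    theta noise is additive Gaussian (sd ``theta_sd``) truncated to [0, 1];
    R noise is multiplicative lognormal with coefficient of variation
    ``r_cv`` and unit mean.  Null (zero-signal) points draw theta uniformly
    on [0, 1] and R from the background level ``r_baseline`` (scaled units:
    a fully hybridising single-copy assay has mean R 1.0) with the same
    multiplicative noise.
    """

    theta_sd: float = 0.02
    r_cv: float = 0.1
    r_baseline: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_sd < 0 or self.r_cv < 0 or self.r_baseline <= 0:
            raise ValueError("noise parameters out of range")


@dataclass
class TruthSet:
    """Ground truth per (marker, sample) produced by the simulator.

    ``frame`` columns: marker, sample, population, genotype (AA/AB/BB, the
    underlying target-site genotype even for null points), x_dose, y_dose,
    null (bool), config (int: 0 for null, 1..k ordering the marker's
    non-null dosage configurations by ascending theta then total dose).
    """

    frame: pd.DataFrame

    def n_configs(self, marker: str) -> int:
        sub = self.frame[self.frame["marker"] == marker]
        return int(sub["config"].nunique())

    def marker(self, marker: str) -> pd.DataFrame:
        return self.frame[self.frame["marker"] == marker].set_index("sample")


def expected_dosage(
    design: AssayDesign, genotype: str, failure_carrier: bool = False
) -> tuple[float, float]:
    """Noise-free channel dosage pair for a sample.

    Each hybridising site contributes two allele doses (one per gene copy);
    a heterozygote contributes one dose of each allele at the target site.
    ``failure_carrier`` marks a sample homozygous for the failure haplotype
    at every site in ``design.failure_sites`` — those sites contribute
    nothing, and if no working site remains the dosage is (0, 0), a null
    point.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"genotype must be one of {GENOTYPES}")
    failed = set(design.failure_sites) if failure_carrier else set()
    x = y = 0.0
    for site in range(design.n_hyb_sites):
        if site in failed:
            continue
        w = design.weight(site)
        if site == design.target_site_index:
            n_b = genotype.count("B")
            x += w * (2 - n_b)
            y += w * n_b
        else:
            if design.fixed_alleles[site] == "A":
                x += 2 * w
            else:
                y += 2 * w
    return x, y


# ---------------------------------------------------------------------------
# genotype sampling
# ---------------------------------------------------------------------------


def _draw_pair(rng, n: int, p: float, inbreeding: float) -> np.ndarray:
    """Draw n haplotype pairs (carrier counts 0/1/2) with inbreeding.

    With probability ``inbreeding`` the two haplotypes are identical by
    descent (a single Bernoulli(p) draw copied), otherwise independent.
    """
    ibd = rng.random(n) < inbreeding
    h1 = rng.random(n) < p
    h2 = np.where(ibd, h1, rng.random(n) < p)
    return h1.astype(int) + h2.astype(int)


def _biparental_dose(
    rng, n: int, a1: int, a2: int, het_rate: float
) -> np.ndarray:
    """Carrier dose (0/1/2) for one unlinked locus in a DH or F4 progeny set.

    ``a1``/``a2`` are the parental carrier states (0 or 1 per haplotype,
    homozygous parents).  Lines inherit one parental state (homozygous)
    chosen 1:1; where the parents differ a fraction ``het_rate`` stays
    heterozygous (dose 1).
    """
    pick = rng.random(n) < 0.5
    dose = np.where(pick, 2 * a1, 2 * a2)
    if a1 != a2 and het_rate > 0:
        het = rng.random(n) < het_rate
        dose = np.where(het, 1, dose)
    return dose.astype(int)


def _draw_founders(rng, design: AssayDesign, p: float) -> tuple[Founder, Founder]:
    founders = []
    for _ in range(2):
        allele = "B" if rng.random() < p else "A"
        failed = frozenset(
            s for s in design.failure_sites if rng.random() < design.failure_freq
        )
        founders.append(Founder(allele=allele, failed_sites=failed))
    return founders[0], founders[1]


def _population_doses(
    rng, design: AssayDesign, pop: PopulationDesign
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Draw (b_dose, working counts per site) for all samples of one pop.

    Returns the target B-allele dose (0/1/2) and, for every site, the count
    of working (non-failed) gene copies (0/1/2).
    """
    n = pop.n_samples
    p = pop.freq(design.marker_id)
    target = design.target_site_index
    working: dict[int, np.ndarray] = {}

    if pop.kind == "diversity":
        b_dose = _draw_pair(rng, n, p, pop.inbreeding)
        for site in range(design.n_hyb_sites):
            if site in design.failure_sites:
                fail = _draw_pair(rng, n, design.failure_freq, pop.inbreeding)
                working[site] = 2 - fail
            else:
                working[site] = np.full(n, 2, dtype=int)
    else:
        if pop.parents is not None and design.marker_id in pop.parents:
            f1, f2 = pop.parents[design.marker_id]
        else:
            f1, f2 = _draw_founders(rng, design, p)
        het = float(pop.het_rate or 0.0)
        b_dose = _biparental_dose(
            rng, n, int(f1.allele == "B"), int(f2.allele == "B"), het
        )
        for site in range(design.n_hyb_sites):
            if site in design.failure_sites:
                fail = _biparental_dose(
                    rng,
                    n,
                    int(site in f1.failed_sites),
                    int(site in f2.failed_sites),
                    het if pop.kind == "F4" else 0.0,
                )
                working[site] = 2 - fail
            else:
                working[site] = np.full(n, 2, dtype=int)
    return b_dose, working


def _doses_to_channels(
    design: AssayDesign, b_dose: np.ndarray, working: dict[int, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Sum per-site allele contributions into (x, y) channel doses."""
    n = len(b_dose)
    x = np.zeros(n)
    y = np.zeros(n)
    target = design.target_site_index
    for site in range(design.n_hyb_sites):
        w_count = working[site].astype(float)
        weight = design.weight(site)
        if site == target:
            # failed target copies silence alleles; heterozygotes with one
            # failed copy keep the allele of the working copy, approximated
            # here by scaling both allele doses by the working fraction
            frac = w_count / 2.0
            x += weight * (2 - b_dose) * frac
            y += weight * b_dose * frac
        else:
            if design.fixed_alleles[site] == "A":
                x += weight * w_count
            else:
                y += weight * w_count
    return x, y


def _config_indices(df: pd.DataFrame) -> np.ndarray:
    """Deterministic cluster-configuration index per row of one marker.

    Null rows get 0; non-null configurations are numbered 1..k by ascending
    noise-free theta, then ascending total dose (distinct intensity levels
    at the same angle are distinct clusters).
    """
    key = list(zip(df["x_dose"], df["y_dose"], df["null"]))
    uniq = sorted(
        set(key),
        key=lambda k: (
            (2.0 / np.pi) * np.arctan2(k[1], k[0]) if not k[2] else -1.0,
            k[0] + k[1],
        ),
    )
    non_null = [k for k in uniq if not k[2]]
    index = {k: i + 1 for i, k in enumerate(non_null)}
    for k in uniq:
        if k[2]:
            index[k] = 0
    return np.array([index[k] for k in key], dtype=int)


def simulate_panel(
    designs: Sequence[AssayDesign],
    pops: Sequence[PopulationDesign],
    noise: NoiseModel,
    seed: int | None = None,
) -> tuple[IntensityPanel, TruthSet]:
    """Simulate a marker x sample intensity panel plus its ground truth.

    Deterministic given the seed (``seed`` argument, else ``noise.seed``):
    identical seeds yield bit-identical panels.  Draw order is fixed as
    markers (in given order) x populations (in given order).
    """
    if not designs:
        raise ValueError("at least one assay design is required")
    if not pops:
        raise ValueError("at least one population is required")
    ids = [d.marker_id for d in designs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate marker_id in designs")
    rng = np.random.default_rng(noise.seed if seed is None else seed)

    sample_ids: list[str] = []
    pop_labels: list[str] = []
    for pop in pops:
        sample_ids.extend(pop.sample_ids())
        pop_labels.extend([pop.pop_id] * pop.n_samples)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids across populations")

    n_total = len(sample_ids)
    theta_mat = np.empty((len(designs), n_total))
    r_mat = np.empty((len(designs), n_total))
    truth_rows = []

    for mi, design in enumerate(designs):
        offset = 0
        marker_truth = []
        for pop in pops:
            n = pop.n_samples
            b_dose, working = _population_doses(rng, design, pop)
            x, y = _doses_to_channels(design, b_dose, working)
            total = x + y
            null = total <= 0

            theta_true = np.zeros(n)
            nz = ~null
            theta_true[nz] = (2.0 / np.pi) * np.arctan2(y[nz], x[nz])

            theta_obs = np.clip(
                theta_true + rng.normal(0.0, noise.theta_sd, n), 0.0, 1.0
            )
            theta_obs[null] = rng.uniform(0.0, 1.0, int(null.sum()))

            sigma = np.sqrt(np.log1p(noise.r_cv**2))
            mult = rng.lognormal(-0.5 * sigma**2, sigma, n)
            r_base = np.where(null, noise.r_baseline, total * R_PER_DOSE)
            r_obs = r_base * mult

            theta_mat[mi, offset : offset + n] = theta_obs
            r_mat[mi, offset : offset + n] = r_obs

            marker_truth.append(
                pd.DataFrame(
                    {
                        "marker": design.marker_id,
                        "sample": sample_ids[offset : offset + n],
                        "population": pop.pop_id,
                        "genotype": np.array(GENOTYPES)[b_dose],
                        "x_dose": x,
                        "y_dose": y,
                        "null": null,
                    }
                )
            )
            offset += n
        mdf = pd.concat(marker_truth, ignore_index=True)
        mdf["config"] = _config_indices(mdf)
        truth_rows.append(mdf)

    samples_meta = pd.DataFrame({"population": pop_labels}, index=pd.Index(sample_ids))
    panel = IntensityPanel(
        theta=pd.DataFrame(theta_mat, index=pd.Index(ids, name="marker"), columns=sample_ids),
        r=pd.DataFrame(r_mat, index=pd.Index(ids, name="marker"), columns=sample_ids),
        samples=samples_meta,
    )
    truth = TruthSet(frame=pd.concat(truth_rows, ignore_index=True))
    return panel, truth
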