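"""Diversity summary statistics on biallelic genotype matrices.

Covers the survey statistics usually reported alongside an array
experiment: per-population MAF spectra and expected/observed
heterozygosity, counts of markers polymorphic in pairs of populations,
Weir & Cockerham's (1984) unbiased pairwise F_ST, and pairwise LD as r².
All functions accept a wide genotype DataFrame (markers x samples, values
AA/AB/BB/NC) and a sample -> population mapping.

Markers carrying null-allele clusters should be excluded upstream — a
hemizygous class breaks the biallelic frequency model these estimators
assume.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "genotype_counts",
    "allele_freq",
    "mean_heterozygosity",
    "weir_cockerham_fst",
    "pairwise_fst",
    "ld_r2",
    "shared_polymorphic",
    "pairwise_stat_table",
    "maf_spectrum",
]

NC = "NC"
_GENO = ("AA", "AB", "BB")


def _check_biallelic(calls: pd.DataFrame) -> None:
    vals = set(pd.unique(calls.values.ravel()))
    bad = vals - set(_GENO) - {NC} - {np.nan, None}
    if bad:
        raise ValueError(f"non-biallelic calls present: {sorted(map(str, bad))[:5]}")


def genotype_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-marker (nAA, nAB, nBB) counts from a wide call matrix."""
    _check_biallelic(calls)
    vals = calls.to_numpy(dtype=object)
    out = {g: (vals == g).sum(axis=1) for g in _GENO}
    return pd.DataFrame(out, index=calls.index)


def allele_freq(calls: pd.DataFrame) -> pd.Series:
    """Per-marker B-allele frequency over non-NC calls (NaN if all NC)."""
    c = genotype_counts(calls)
    n = c.sum(axis=1)
    with np.errstate(invalid="ignore"):
        return ((c["AB"] + 2 * c["BB"]) / (2 * n)).where(n > 0)


def mean_heterozygosity(
    calls: pd.DataFrame,
    partition: pd.Series,
    kind: str = "expected",
) -> pd.Series:
    """Average heterozygosity per population over its polymorphic markers.

    ``kind='expected'`` averages the gene diversity 2p(1-p) computed from
    each population's own allele frequencies; ``kind='observed'`` averages
    the heterozygote call fraction.  Populations with no polymorphic marker
    come back NaN (undefined).
    """
    if kind not in ("expected", "observed"):
        raise ValueError("kind must be 'expected' or 'observed'")
    out = {}
    for pop, samples in _pop_groups(calls, partition):
        sub = calls[samples]
        p = allele_freq(sub)
        poly = p.notna() & (p > 0) & (p < 1)
        if not poly.any():
            out[pop] = np.nan
            continue
        if kind == "expected":
            h = 2 * p[poly] * (1 - p[poly])
        else:
            c = genotype_counts(sub.loc[poly])
            n = c.sum(axis=1)
            h = (c["AB"] / n).where(n > 0)
        out[pop] = float(h.mean())
    return pd.Series(out, name=f"{kind}_heterozygosity")


def _pop_groups(calls: pd.DataFrame, partition: pd.Series):
    partition = partition.reindex(calls.columns)
    if partition.isna().any():
        missing = list(partition.index[partition.isna()])[:5]
        raise ValueError(f"samples without population label: {missing}")
    for pop in sorted(partition.unique()):
        yield pop, list(partition.index[partition == pop])


def weir_cockerham_fst(
    counts1: pd.DataFrame | np.ndarray, counts2: pd.DataFrame | np.ndarray
) -> float:
    """Weir & Cockerham (1984) unbiased theta-hat between two populations.

    Inputs are per-marker genotype counts (columns nAA, nAB, nBB) for each
    population.  The multi-marker estimate is the ratio of summed variance
    components sum(a) / sum(a + b + c); it can be slightly negative for
    undifferentiated populations.  Markers lacking data in either
    population are dropped; a zero total variance leaves the estimate
    undefined (NaN).
    """
    c1 = np.asarray(counts1, dtype=float).reshape(-1, 3)
    c2 = np.asarray(counts2, dtype=float).reshape(-1, 3)
    if c1.shape != c2.shape:
        raise ValueError("count tables must align marker-wise")
    n1 = c1.sum(axis=1)
    n2 = c2.sum(axis=1)
    keep = (n1 > 0) & (n2 > 0)
    if not keep.any():
        raise ValueError("no marker typed in both populations")
    c1, c2, n1, n2 = c1[keep], c2[keep], n1[keep], n2[keep]

    r = 2.0
    p1 = (c1[:, 1] + 2 * c1[:, 2]) / (2 * n1)
    p2 = (c2[:, 1] + 2 * c2[:, 2]) / (2 * n2)
    h1 = c1[:, 1] / n1
    h2 = c2[:, 1] / n2

    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    valid = nbar > 1
    nbar, nc, pbar, s2, hbar = (v[valid] for v in (nbar, nc, pbar, s2, hbar))
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    denom = float((a + b + c).sum())
    if denom == 0:
        return float("nan")
    return float(a.sum() / denom)


def pairwise_fst(calls: pd.DataFrame, partition: pd.Series) -> pd.DataFrame:
    """Symmetric matrix of pairwise Weir-Cockerham theta-hat estimates."""
    groups = dict(_pop_groups(calls, partition))
    pops = list(groups)
    counts = {pop: genotype_counts(calls[groups[pop]]) for pop in pops}
    out = pd.DataFrame(np.nan, index=pops, columns=pops, dtype=float)
    for i, p in enumerate(pops):
        out.loc[p, p] = 0.0
        for q in pops[i + 1 :]:
            theta = weir_cockerham_fst(counts[p], counts[q])
            out.loc[p, q] = out.loc[q, p] = theta
    return out


def ld_r2(
    calls_i: pd.Series, calls_j: pd.Series, with_method: bool = False
):
    """Squared allelic correlation (r²) between two biallelic markers.

    On fully homozygous data the phase is known: genotypes are haplotypes
    and r² = D² / (pA pa pB pb) from direct haplotype counts.  When
    heterozygotes are present phase is unknown and r² falls back to the
    squared Pearson correlation of allele dosages.  NC entries are dropped
    pairwise; a monomorphic marker leaves r² undefined (ValueError).
    """
    pair = pd.DataFrame({"i": calls_i, "j": calls_j})
    pair = pair[(pair["i"] != NC) & (pair["j"] != NC)].dropna()
    for col in ("i", "j"):
        bad = set(pair[col].unique()) - set(_GENO)
        if bad:
            raise ValueError(f"non-biallelic calls: {sorted(bad)}")
    dose = pair.apply(lambda s: s.map({"AA": 0, "AB": 1, "BB": 2})).astype(int)
    if dose["i"].nunique() < 2 or dose["j"].nunique() < 2:
        raise ValueError("r2 undefined for a monomorphic marker")

    if (dose["i"] == 1).any() or (dose["j"] == 1).any():
        rho = float(np.corrcoef(dose["i"], dose["j"])[0, 1])
        r2, method = rho**2, "genotype_correlation"
    else:
        hap = dose // 2  # homozygous: genotype determines both haplotypes
        n = len(hap)
        p_b_i = float(hap["i"].mean())
        p_b_j = float(hap["j"].mean())
        p_bb = float(((hap["i"] == 1) & (hap["j"] == 1)).mean())
        d = p_bb - p_b_i * p_b_j
        denom = p_b_i * (1 - p_b_i) * p_b_j * (1 - p_b_j)
        r2, method = d**2 / denom, "haplotype"
    return (float(r2), method) if with_method else float(r2)


def shared_polymorphic(
    calls: pd.DataFrame, partition: pd.Series, maf_floor: float = 0.0
) -> pd.DataFrame:
    """Markers polymorphic (MAF > maf_floor) in both populations of a pair."""
    groups = dict(_pop_groups(calls, partition))
    poly = {}
    for pop, samples in groups.items():
        p = allele_freq(calls[samples])
        m = np.minimum(p, 1 - p)
        poly[pop] = (m > maf_floor).fillna(False)
    pops = list(groups)
    out = pd.DataFrame(0, index=pops, columns=pops, dtype=int)
    for i, p in enumerate(pops):
        for q in pops[i:]:
            n = int((poly[p] & poly[q]).sum())
            out.loc[p, q] = out.loc[q, p] = n
    return out


def pairwise_stat_table(
    calls: pd.DataFrame, partition: pd.Series, maf_floor: float = 0.0
) -> pd.DataFrame:
    """Combined population-pair table: shared counts above the diagonal,
    Weir-Cockerham F_ST below, zeros on the diagonal."""
    shared = shared_polymorphic(calls, partition, maf_floor)
    fst = pairwise_fst(calls, partition)
    pops = list(shared.index)
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, p in enumerate(pops):
        for j, q in enumerate(pops):
            if i < j:
                out.loc[p, q] = float(shared.loc[p, q])
            elif i > j:
                out.loc[p, q] = float(fst.loc[p, q])
    return out


def maf_spectrum(
    calls: pd.DataFrame, partition: pd.Series, bins: Iterable[float] | None = None
) -> pd.DataFrame:
    """Histogram of per-marker MAF per population (polymorphic markers)."""
    if bins is None:
        bins = np.arange(0.0, 0.55, 0.05)
    bins = np.asarray(list(bins))
    out = {}
    for pop, samples in _pop_groups(calls, partition):
        p = allele_freq(calls[samples]).dropna()
        m = np.minimum(p, 1 - p)
        m = m[m > 0]
        hist, _ = np.histogram(m, bins=bins)
        out[pop] = hist
    labels = [f"({bins[i]:.2f},{bins[i+1]:.2f}]" for i in range(len(bins) - 1)]
    return pd.DataFrame(out, index=labels)
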