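"""Resolve multi-cluster assays into biallelic loci via bi-parental crosses.

An assay whose probe hybridises to several polymorphic gene copies shows
more than three clusters in a diverse panel, but within one bi-parental
population only a single locus usually segregates, so the population's
samples split between exactly *two* of the clusters.  Tracking which
cluster pair segregates in which population links clusters that behave as
alternative alleles of one locus; a cluster shared by pairs from different
populations (a hub) is the common state both crosses return to — e.g. the
probe-failure class that one cross segregates against a target-SNP allele
while another cross segregates against the secondary probe-site
polymorphism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import NC, GenotypeMatrix

__all__ = ["SegregationRecord", "AllelicMap", "detect_segregation", "build_allelic_map"]


@dataclass(frozen=True)
class SegregationRecord:
    """One population segregating between two clusters at one marker."""

    marker: str
    population: str
    cluster_a: str
    cluster_b: str
    n_a: int
    n_b: int
    p_value: float  # chi-square against the expected 1:1 DH ratio (annotation only)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.cluster_a, self.cluster_b)


@dataclass
class AllelicMap:
    """Cluster-level allelic structure of one marker.

    ``edges`` are (cluster_a, cluster_b, population) triples, one per
    biallelic locus observation; ``hubs`` are clusters incident to edges
    from more than one population (shared allele states); ``unresolved``
    lists observed clusters with no incident edge.  ``conflict`` marks
    contradictory records (same population claiming different pairs).
    """

    marker: str
    edges: list[tuple[str, str, str]] = field(default_factory=list)
    hubs: list[str] = field(default_factory=list)
    unresolved: list[str] = field(default_factory=list)
    conflict: bool = False

    @property
    def n_loci(self) -> int:
        return len({frozenset((a, b)) for a, b, _ in self.edges})


def detect_segregation(
    calls: pd.Series,
    marker: str,
    population: str,
    min_points: int = 10,
    combined_freq: float = 0.90,
) -> SegregationRecord | None:
    """Find the cluster pair a population segregates between, if any.

    ``calls`` maps sample -> cluster label for this population at this
    marker (NC entries are ignored).  A pair qualifies when its combined
    frequency among called samples is at least ``combined_freq`` and both
    clusters hold at least ``min_points`` samples.  Returns None for
    monomorphic or messier patterns.  The chi-square p-value against a 1:1
    ratio (the doubled-haploid expectation) is recorded as annotation, not
    used as a filter — distorted ratios occur in regions of restricted
    recombination.
    """
    counts = calls[calls != NC].value_counts()
    if len(counts) < 2:
        return None
    top = counts.iloc[:2]
    if top.min() < min_points:
        return None
    if top.sum() / counts.sum() < combined_freq:
        return None
    a, b = sorted(top.index[:2])
    n_a, n_b = int(counts[a]), int(counts[b])
    p = float(stats.chisquare([n_a, n_b]).pvalue)
    return SegregationRecord(
        marker=marker, population=population, cluster_a=a, cluster_b=b,
        n_a=n_a, n_b=n_b, p_value=p,
    )


def segregation_records(
    genotypes: GenotypeMatrix,
    populations: pd.Series,
    min_points: int = 10,
    combined_freq: float = 0.90,
) -> list[SegregationRecord]:
    """Scan every (marker, population) for segregating cluster pairs.

    ``populations`` maps sample id -> population label; only bi-parental
    populations should be included.  Uses the ``cluster`` column of the
    genotype matrix so the result is independent of biallelic genotype
    labelling.
    """
    records = []
    frame = genotypes.frame.copy()
    frame["population"] = frame["sample"].map(populations)
    frame = frame.dropna(subset=["population"])
    for (marker, pop), sub in frame.groupby(["marker", "population"], sort=True):
        rec = detect_segregation(
            sub.set_index("sample")["cluster"], str(marker), str(pop),
            min_points=min_points, combined_freq=combined_freq,
        )
        if rec is not None:
            records.append(rec)
    return records


def build_allelic_map(
    records: Iterable[SegregationRecord],
    observed_clusters: dict[str, Sequence[str]] | None = None,
) -> dict[str, AllelicMap]:
    """Assemble per-marker allelic maps from segregation records.

    Clusters are nodes, each record contributes an edge (one biallelic
    locus observation).  Hub nodes — incident to edges from at least two
    distinct populations — are shared allele states.  ``observed_clusters``
    (marker -> all cluster labels fitted for that marker) lets clusters
    with no incident edge be reported as unresolved.  Conflicting records
    (one population, one marker, different pairs) flag the marker as
    unresolved with ``conflict=True``.  The result is independent of record
    order.
    """
    if observed_clusters is not None and hasattr(observed_clusters, "markers"):
        observed_clusters = {
            m: [c.ordinal for c in cl]
            for m, cl in observed_clusters.markers.items()  # type: ignore[union-attr]
        }
    by_marker: dict[str, list[SegregationRecord]] = {}
    for rec in records:
        by_marker.setdefault(rec.marker, []).append(rec)

    out: dict[str, AllelicMap] = {}
    markers = set(by_marker)
    if observed_clusters:
        markers |= set(observed_clusters)
    for marker in sorted(markers):
        recs = sorted(
            by_marker.get(marker, []), key=lambda r: (r.population, r.pair)
        )
        amap = AllelicMap(marker=marker)
        seen_pops: dict[str, tuple[str, str]] = {}
        for rec in recs:
            prior = seen_pops.get(rec.population)
            if prior is not None and prior != rec.pair:
                amap.conflict = True
            seen_pops.setdefault(rec.population, rec.pair)
        if amap.conflict:
            amap.unresolved = sorted(
                set(observed_clusters.get(marker, [])) if observed_clusters else
                {c for r in recs for c in r.pair}
            )
            out[marker] = amap
            continue
        pops_at_node: dict[str, set[str]] = {}
        for rec in recs:
            amap.edges.append((rec.cluster_a, rec.cluster_b, rec.population))
            for node in rec.pair:
                pops_at_node.setdefault(node, set()).add(rec.population)
        amap.hubs = sorted(n for n, pops in pops_at_node.items() if len(pops) >= 2)
        observed = (
            set(observed_clusters.get(marker, [])) if observed_clusters else set()
        )
        amap.unresolved = sorted(observed - set(pops_at_node))
        out[marker] = amap
    return out
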