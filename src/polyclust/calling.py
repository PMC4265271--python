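"""Three-step density-based genotype-calling protocol for polyploid arrays.

Per assay the protocol runs:

1. DBSCAN with cluster distance 0.07 and a 10-point cluster minimum, then
   filters on cluster count, call rate and minor-allele frequency (MAF);
2. assays that yielded a *single* cluster are re-clustered with OPTICS at
   the same density settings and a forced two-cluster extraction — this
   splits closely spaced clusters produced by duplicated gene copies
   (cluster compression);
3. assays still unsatisfactory are re-clustered with DBSCAN at cluster
   distance 0.09 to capture clusters too broad for the first pass.

After the accepted step, every sample is assigned to a cluster with a
Gaussian-responsibility confidence score and called only when the score
reaches the confidence limit (default 0.8).  Clusters are named C1..Cn by
ascending theta; an assay with exactly three non-null clusters is
interpreted as a biallelic SNP (AA / AB / BB by ascending theta).  Clusters
whose median intensity falls far below the assay's strongest cluster are
flagged as null-allele clusters (gene deletion or probe-site divergence)
and their members are called NULL.

Clustering operates on scaled coordinates: theta as-is, and R divided by
the marker's 95th intensity percentile and down-weighted (default 0.25) so
intensity scatter does not dominate the angular separation while
presence/absence contrast still isolates null clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cluster_core import (
    NOISE,
    ClusterLabeling,
    DensityParams,
    PointSet,
    dbscan,
    extract_k_clusters,
    optics,
)
from .panel import IntensityPanel

__all__ = [
    "FilterSpec",
    "ProtocolParams",
    "ClusterInfo",
    "ClusterModel",
    "GenotypeMatrix",
    "StepReport",
    "maf",
    "filter_assay",
    "build_clusters",
    "label_clusters",
    "detect_null_clusters",
    "assign_samples",
    "run_protocol",
    "apply_model",
]

NC = "NC"
NULL_CALL = "NULL"
BIALLELIC = ("AA", "AB", "BB")

#: fixed decimal quantum for persisted model/confidence values
_DECIMALS = 6


def _q(x: float) -> float:
    return float(round(float(x), _DECIMALS))


@dataclass(frozen=True)
class FilterSpec:
    """Assay-level filters: cluster-count window, call rate and MAF floors."""

    cluster_range: tuple[int, int] = (2, 6)
    call_rate_min: float = 0.90
    maf_min: float = 0.05


@dataclass
class ProtocolParams:
    """All tunables of the three-step protocol.

    Step density parameters default to the published settings (0.07/10 for
    steps 1-2, 0.09/10 for step 3, two forced clusters at step 2); the
    confidence limit defaults to 0.8.  ``maf_min`` is 0.35 in ``mapping``
    mode (bi-parental populations) and 0.05 in ``diversity`` mode
    (unrelated accessions).  Cluster-count windows and the 0.90 call-rate
    floor are configurable defaults.
    """

    step1: DensityParams = field(default_factory=lambda: DensityParams(0.07, 10))
    step2: DensityParams = field(default_factory=lambda: DensityParams(0.07, 10))
    step3: DensityParams = field(default_factory=lambda: DensityParams(0.09, 10))
    step2_k: int = 2
    confidence_limit: float = 0.8
    maf_min: float = 0.05
    call_rate_min: float = 0.90
    step1_cluster_range: tuple[int, int] = (2, 6)
    step2_cluster_range: tuple[int, int] = (2, 2)
    step3_cluster_range: tuple[int, int] = (2, 6)
    r_axis_weight: float = 0.25
    null_r_ratio: float = 0.25
    spread_floor: float = 0.01
    max_std_distance: float = 6.0

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "ProtocolParams":
        if mode == "mapping":
            maf_min = 0.35
        elif mode == "diversity":
            maf_min = 0.05
        else:
            raise ValueError(f"unknown mode {mode!r}; use 'mapping' or 'diversity'")
        return cls(maf_min=maf_min, **overrides)

    def filter_spec(self, step: int) -> FilterSpec:
        rng = {
            1: self.step1_cluster_range,
            2: self.step2_cluster_range,
            3: self.step3_cluster_range,
        }[step]
        return FilterSpec(
            cluster_range=rng, call_rate_min=self.call_rate_min, maf_min=self.maf_min
        )


@dataclass
class ClusterInfo:
    """One fitted cluster of one assay, in (theta, scaled-R) coordinates."""

    ordinal: str  # C1..Cn by ascending theta
    center_theta: float
    center_r: float
    spread_theta: float
    spread_r: float
    n: int
    null: bool = False
    genotype: str | None = None  # AA/AB/BB for biallelic assays

    @property
    def call_label(self) -> str:
        if self.null:
            return NULL_CALL
        return self.genotype if self.genotype is not None else self.ordinal


@dataclass
class ClusterModel:
    """Per-marker fitted clusters — the persistable calling model."""

    markers: dict[str, list[ClusterInfo]] = field(default_factory=dict)
    version: int = 1

    def n_clusters(self, marker: str) -> int:
        return len(self.markers[marker])

    def is_biallelic(self, marker: str) -> bool:
        return any(c.genotype is not None for c in self.markers[marker])

    def __contains__(self, marker: str) -> bool:
        return marker in self.markers

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ClusterModel)
            and self.version == other.version
            and self.markers == other.markers
        )


@dataclass
class GenotypeMatrix:
    """Long-format calls: one row per (marker, sample).

    Columns: marker, sample, call (AA/AB/BB, C1..Cn, NULL or NC), cluster
    (assigned ordinal, NULL-flagged clusters keep their ordinal; NC when
    unassigned), confidence in [0, 1].
    """

    frame: pd.DataFrame

    def wide(self, value: str = "call") -> pd.DataFrame:
        w = self.frame.pivot(index="marker", columns="sample", values=value)
        return w.sort_index().sort_index(axis=1)

    def marker_calls(self, marker: str) -> pd.Series:
        sub = self.frame[self.frame["marker"] == marker]
        return sub.set_index("sample")["call"]

    def n_called(self) -> int:
        return int((self.frame["call"] != NC).sum())

    def sorted(self) -> "GenotypeMatrix":
        f = self.frame.sort_values(["marker", "sample"], kind="mergesort")
        return GenotypeMatrix(f.reset_index(drop=True))


@dataclass
class StepReport:
    """Per-marker protocol accounting.

    ``frame`` columns: marker, status ('1'/'2'/'3' for the accepted step or
    'failed'), n_clusters, history (';'-joined per-step outcomes, e.g.
    ``1:fail[cluster_number]  2:pass``), reasons (final failure reasons).
    """

    frame: pd.DataFrame

    def step_counts(self) -> dict[str, int]:
        return self.frame["status"].value_counts().to_dict()

    def accepted(self) -> pd.DataFrame:
        return self.frame[self.frame["status"] != "failed"]


# ---------------------------------------------------------------------------
# assay-level statistics
# ---------------------------------------------------------------------------


def maf(calls: Iterable[str], return_kind: bool = False):
    """Minor-allele frequency of one assay's calls.

    Biallelic calls (AA/AB/BB, ignoring NULL and NC) yield the allele-count
    minimum with heterozygotes contributing one copy of each allele.  Calls
    on cluster ordinals (C1..Cn, plus NULL as its own class) instead yield
    the minimum cluster frequency — flagged as 'cluster' MAF.  All-NC input
    raises ValueError.
    """
    vals = pd.Series(list(calls), dtype=object)
    vals = vals[vals != NC]
    if vals.empty:
        raise ValueError("MAF undefined: no non-NC calls")
    labels = set(vals.unique())
    if labels <= set(BIALLELIC) | {NULL_CALL}:
        geno = vals[vals != NULL_CALL]
        if geno.empty:
            value, kind = 0.0, "biallelic"
        else:
            n_b = (geno == "AB").sum() + 2 * (geno == "BB").sum()
            freq = n_b / (2 * len(geno))
            value, kind = float(min(freq, 1.0 - freq)), "biallelic"
    else:
        counts = vals.value_counts()
        value, kind = float(counts.min() / counts.sum()), "cluster"
    return (value, kind) if return_kind else value


def filter_assay(
    calls: Iterable[str], spec: FilterSpec, n_clusters: int | None = None
) -> tuple[bool, list[str]]:
    """Apply cluster-number / call-rate / MAF filters to one assay.

    Returns (pass, reasons); reasons name every failed criterion.  The
    cluster count is taken from the fitted model when given, else from the
    distinct non-NC call labels.
    """
    vals = pd.Series(list(calls), dtype=object)
    if n_clusters is None:
        n_clusters = vals[vals != NC].nunique()
    reasons = []
    lo, hi = spec.cluster_range
    if not lo <= n_clusters <= hi:
        reasons.append("cluster_number")
    call_rate = float((vals != NC).mean()) if len(vals) else 0.0
    if call_rate < spec.call_rate_min:
        reasons.append("call_rate")
    try:
        value = maf(vals)
    except ValueError:
        value = 0.0
    if value < spec.maf_min:
        reasons.append("maf")
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------


def _robust_spread(values: np.ndarray, floor: float) -> float:
    mad = np.median(np.abs(values - np.median(values)))
    return max(1.4826 * float(mad), floor)


def build_clusters(
    labeling: ClusterLabeling,
    theta: np.ndarray,
    r_scaled: np.ndarray,
    spread_floor: float = 0.01,
) -> list[ClusterInfo]:
    """Summarise a labeling into per-cluster centers and robust spreads.

    Centers are medians, spreads are scaled median absolute deviations
    (floored), both quantised to 6 decimals so an in-memory model is
    bit-identical to its serialised form.
    """
    clusters = []
    for c in range(1, labeling.n_clusters + 1):
        idx = labeling.members(c)
        if len(idx) == 0:
            continue
        clusters.append(
            ClusterInfo(
                ordinal="C?",
                center_theta=_q(np.median(theta[idx])),
                center_r=_q(np.median(r_scaled[idx])),
                spread_theta=_q(_robust_spread(theta[idx], spread_floor)),
                spread_r=_q(_robust_spread(r_scaled[idx], spread_floor)),
                n=int(len(idx)),
            )
        )
    return clusters


def label_clusters(clusters: list[ClusterInfo]) -> list[ClusterInfo]:
    """Order clusters by ascending theta (then intensity) and name them.

    All clusters, null-flagged ones included, receive ordinals C1..Cn.
    When exactly three non-null clusters remain they are additionally
    interpreted as the biallelic genotypes AA (lowest theta), AB, BB.
    """
    ordered = sorted(clusters, key=lambda c: (c.center_theta, c.center_r))
    for i, c in enumerate(ordered):
        c.ordinal = f"C{i + 1}"
        c.genotype = None
    non_null = [c for c in ordered if not c.null]
    if len(non_null) == 3:
        for c, g in zip(non_null, BIALLELIC):
            c.genotype = g
    return ordered


def detect_null_clusters(
    clusters: list[ClusterInfo], r_ratio: float = 0.25
) -> list[ClusterInfo]:
    """Flag low-intensity (null-allele) clusters.

    A cluster is null when its median scaled intensity is below ``r_ratio``
    times the largest cluster median of the assay.  Needs at least two
    clusters — a lone cluster has no reference level.
    """
    if len(clusters) >= 2:
        r_max = max(c.center_r for c in clusters)
        for c in clusters:
            c.null = r_max > 0 and c.center_r < r_ratio * r_max
    return clusters


def _fit_marker(
    labeling: ClusterLabeling,
    theta: np.ndarray,
    r_scaled: np.ndarray,
    params: ProtocolParams,
) -> list[ClusterInfo]:
    clusters = build_clusters(labeling, theta, r_scaled, params.spread_floor)
    clusters = detect_null_clusters(clusters, params.null_r_ratio)
    return label_clusters(clusters)


# ---------------------------------------------------------------------------
# sample assignment
# ---------------------------------------------------------------------------


def assign_samples(
    clusters: Sequence[ClusterInfo],
    theta: np.ndarray,
    r_scaled: np.ndarray,
    confidence_limit: float = 0.8,
    max_std_distance: float = 6.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign points to clusters with a Gaussian-responsibility confidence.

    For each cluster k the weight is w_k = exp(-d_k^2 / 2) with d_k the
    per-axis spread-standardised distance to the cluster center; the
    confidence is max_k w_k / sum_k w_k.  A sample is called when the
    confidence reaches ``confidence_limit`` and its nearest cluster lies
    within ``max_std_distance`` standardised units (points far outside the
    trained model — e.g. a cluster absent from training — stay NC).

    Returns (call, cluster_ordinal, confidence) arrays.
    """
    if not clusters:
        raise ValueError("model has no clusters")
    n = len(theta)
    d2 = np.empty((len(clusters), n))
    for k, c in enumerate(clusters):
        d2[k] = ((theta - c.center_theta) / c.spread_theta) ** 2 + (
            (r_scaled - c.center_r) / c.spread_r
        ) ** 2
    d2min = d2.min(axis=0)
    best = d2.argmin(axis=0)
    # stable responsibility: 1 / sum_k exp((d2min - d2_k)/2)
    conf = 1.0 / np.exp((d2min - d2) / 2.0).sum(axis=0)
    conf = np.round(conf, _DECIMALS)

    out_call = np.empty(n, dtype=object)
    out_cluster = np.empty(n, dtype=object)
    reachable = d2min <= max_std_distance**2
    called = (conf >= confidence_limit) & reachable
    for i in range(n):
        if called[i]:
            c = clusters[best[i]]
            out_call[i] = c.call_label
            out_cluster[i] = c.ordinal
        else:
            out_call[i] = NC
            out_cluster[i] = NC
    conf = np.where(reachable, conf, 0.0)
    return out_call, out_cluster, conf


# ---------------------------------------------------------------------------
# the protocol
# ---------------------------------------------------------------------------


def _scaled_coords(r: np.ndarray) -> np.ndarray:
    p95 = float(np.percentile(r, 95))
    if p95 <= 0:
        p95 = max(float(r.max()), 1e-9)
    return r / p95


def _attempt(
    step: int,
    labeling: ClusterLabeling,
    theta: np.ndarray,
    r_scaled: np.ndarray,
    params: ProtocolParams,
):
    clusters = _fit_marker(labeling, theta, r_scaled, params)
    if clusters:
        call, cluster, conf = assign_samples(
            clusters,
            theta,
            r_scaled,
            params.confidence_limit,
            params.max_std_distance,
        )
    else:
        n = len(theta)
        call = np.full(n, NC, dtype=object)
        cluster = np.full(n, NC, dtype=object)
        conf = np.zeros(n)
    ok, reasons = filter_assay(call, params.filter_spec(step), n_clusters=len(clusters))
    return clusters, call, cluster, conf, ok, reasons


def run_protocol(
    panel: IntensityPanel,
    params: ProtocolParams | None = None,
    mode: str | None = None,
) -> tuple[ClusterModel, GenotypeMatrix, StepReport]:
    """Run the full three-step protocol over a panel.

    Pass either ready-made ``params`` or a ``mode`` ('mapping' or
    'diversity') selecting the published MAF floor.  Returns the fitted
    cluster model (accepted markers only), the genotype matrix and the
    per-marker step report; every marker ends in exactly one terminal
    status.
    """
    if params is None:
        params = ProtocolParams.for_mode(mode or "diversity")
    elif mode is not None:
        params = replace(params, maf_min=ProtocolParams.for_mode(mode).maf_min)

    model = ClusterModel()
    geno_rows = []
    report_rows = []

    for marker in panel.markers:
        theta, r, samp = panel.marker_points(marker)
        if len(theta) == 0:
            report_rows.append(
                dict(marker=marker, status="failed", n_clusters=0, history="no_data",
                     reasons="no_data")
            )
            continue
        r_scaled = _scaled_coords(r)
        pts = PointSet(
            np.column_stack([theta, params.r_axis_weight * r_scaled]),
            sample_ids=np.asarray(samp),
        )

        history = []
        accepted = None
        # step 1: DBSCAN at the tight radius
        lab1 = dbscan(pts, params.step1)
        res1 = _attempt(1, lab1, theta, r_scaled, params)
        history.append(_hist(1, res1))
        if res1[4]:
            accepted = (1, res1)
        else:
            routed_step2 = lab1.n_clusters == 1
            res2 = None
            if routed_step2:
                # step 2: OPTICS + forced-k split of a compressed cluster
                profile = optics(pts, params.step2)
                lab2 = extract_k_clusters(profile, params.step2_k, params.step2)
                res2 = _attempt(2, lab2, theta, r_scaled, params)
                history.append(_hist(2, res2))
                if res2[4]:
                    accepted = (2, res2)
            if accepted is None:
                # step 3: DBSCAN at the broad radius
                lab3 = dbscan(pts, params.step3)
                res3 = _attempt(3, lab3, theta, r_scaled, params)
                history.append(_hist(3, res3))
                if res3[4]:
                    accepted = (3, res3)
                else:
                    final_reasons = res3[5]

        if accepted is None:
            report_rows.append(
                dict(
                    marker=marker,
                    status="failed",
                    n_clusters=0,
                    history="  ".join(history),
                    reasons=",".join(final_reasons),
                )
            )
            continue

        step, (clusters, call, cluster, conf, _, _) = accepted
        model.markers[marker] = clusters
        geno_rows.append(
            pd.DataFrame(
                {
                    "marker": marker,
                    "sample": np.asarray(samp),
                    "call": call,
                    "cluster": cluster,
                    "confidence": conf,
                }
            )
        )
        # samples dropped for missing intensities are reported NC
        missing = panel.sample_ids.difference(samp)
        if len(missing):
            geno_rows.append(
                pd.DataFrame(
                    {
                        "marker": marker,
                        "sample": np.asarray(missing),
                        "call": NC,
                        "cluster": NC,
                        "confidence": 0.0,
                    }
                )
            )
        report_rows.append(
            dict(
                marker=marker,
                status=str(step),
                n_clusters=len(clusters),
                history="  ".join(history),
                reasons="",
            )
        )

    geno = (
        pd.concat(geno_rows, ignore_index=True)
        if geno_rows
        else pd.DataFrame(columns=["marker", "sample", "call", "cluster", "confidence"])
    )
    matrix = GenotypeMatrix(geno).sorted()
    report = StepReport(pd.DataFrame(report_rows))
    return model, matrix, report


def _hist(step: int, res) -> str:
    ok, reasons = res[4], res[5]
    return f"{step}:pass" if ok else f"{step}:fail[{'+'.join(reasons) or 'none'}]"


def apply_model(
    model: ClusterModel,
    panel: IntensityPanel,
    confidence_limit: float = 0.8,
    max_std_distance: float = 6.0,
) -> GenotypeMatrix:
    """Genotype a panel with a stored cluster model, without re-clustering.

    This is the cluster-file workflow: train the model on mapping
    populations, then apply it to new accessions.  Samples falling in a
    cluster absent from the trained model end up far from every stored
    center and are reported NC.
    """
    rows = []
    for marker in panel.markers:
        if marker not in model:
            continue
        theta, r, samp = panel.marker_points(marker)
        if len(theta) == 0:
            continue
        r_scaled = _scaled_coords(r)
        call, cluster, conf = assign_samples(
            model.markers[marker], theta, r_scaled, confidence_limit, max_std_distance
        )
        rows.append(
            pd.DataFrame(
                {
                    "marker": marker,
                    "sample": np.asarray(samp),
                    "call": call,
                    "cluster": cluster,
                    "confidence": conf,
                }
            )
        )
    geno = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["marker", "sample", "call", "cluster", "confidence"])
    )
    return GenotypeMatrix(geno).sorted()
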