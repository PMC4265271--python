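"""Comparing calls and fitted models against simulator ground truth.

The simulator's :class:`~polyclust.signal_sim.TruthSet` records, per point,
the generating dosage configuration (an integer: 0 for null, 1..k by
ascending theta).  Fitted cluster labels are arbitrary, so concordance is
measured after mapping each fitted cluster to the truth configuration of
the majority of its members — the standard cluster-recovery accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import NC, NULL_CALL, ClusterModel, GenotypeMatrix
from .signal_sim import TruthSet

__all__ = ["CallAccuracy", "call_accuracy", "NullMetrics", "null_detection_metrics",
           "split_accuracy"]


@dataclass
class CallAccuracy:
    concordance: float  # fraction of non-NC calls matching truth configuration
    nc_rate: float
    n_calls: int
    n_nc: int


def call_accuracy(genotypes: GenotypeMatrix, truth: TruthSet) -> CallAccuracy:
    """Majority-mapped concordance of non-NC calls plus the NC rate.

    Per marker, each assigned cluster ordinal is mapped to the truth
    configuration held by the majority of its called members; a call is
    concordant when its sample's configuration matches its cluster's
    mapped configuration.  The NC rate is computed over all emitted calls.
    """
    merged = genotypes.frame.merge(
        truth.frame[["marker", "sample", "config"]], on=["marker", "sample"],
        how="left", validate="one_to_one",
    )
    if merged["config"].isna().any():
        raise ValueError("truth does not cover all called (marker, sample) pairs")
    n_total = len(merged)
    called = merged[merged["cluster"] != NC].copy()
    n_nc = n_total - len(called)
    if called.empty:
        return CallAccuracy(float("nan"), 1.0, 0, n_nc)
    majority = (
        called.groupby(["marker", "cluster"])["config"]
        .agg(lambda s: s.value_counts().idxmax())
        .rename("mapped")
    )
    called = called.join(majority, on=["marker", "cluster"])
    conc = float((called["config"] == called["mapped"]).mean())
    return CallAccuracy(conc, n_nc / n_total, len(called), n_nc)


@dataclass
class NullMetrics:
    sensitivity: float  # flagged fraction of truly-null fitted clusters
    false_flag_rate: float  # flagged fraction of non-null fitted clusters
    n_true_null_clusters: int
    n_other_clusters: int


def null_detection_metrics(
    model: ClusterModel, genotypes: GenotypeMatrix, truth: TruthSet
) -> NullMetrics:
    """Cluster-level null-allele detection quality against the truth.

    A fitted cluster is *truly null* when the majority of its assigned
    members are simulated zero-signal points.  Sensitivity is the flagged
    fraction of truly-null clusters; the false-flag rate is the flagged
    fraction of all other clusters.
    """
    merged = genotypes.frame.merge(
        truth.frame[["marker", "sample", "null"]], on=["marker", "sample"], how="left"
    )
    called = merged[merged["cluster"] != NC]
    null_frac = called.groupby(["marker", "cluster"])["null"].mean()

    tp = fn = fp = tn = 0
    for marker, clusters in model.markers.items():
        for c in clusters:
            frac = null_frac.get((marker, c.ordinal), 0.0)
            truly_null = frac > 0.5
            if truly_null and c.null:
                tp += 1
            elif truly_null:
                fn += 1
            elif c.null:
                fp += 1
            else:
                tn += 1
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    ffr = fp / (fp + tn) if (fp + tn) else 0.0
    return NullMetrics(sens, ffr, tp + fn, fp + tn)


def split_accuracy(labels: np.ndarray, truth_config: np.ndarray) -> float:
    """Best-permutation accuracy of a two-way (or k-way) split.

    Maps each predicted label (noise included, as its own class) to the
    majority truth configuration and returns the fraction of points whose
    truth matches the mapped label; unclustered points under a mapped
    noise class count as errors unless noise happens to align.
    """
    labels = np.asarray(labels)
    truth_config = np.asarray(truth_config)
    correct = 0
    for lab in np.unique(labels):
        mask = labels == lab
        if lab == -1:  # noise: never credited
            continue
        vals, counts = np.unique(truth_config[mask], return_counts=True)
        correct += int(counts.max())
    return correct / len(labels)
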