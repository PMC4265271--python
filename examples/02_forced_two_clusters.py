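"""Split a compressed cluster pair with the forced-k OPTICS extraction.

A probe hybridising to seven gene copies leaves only ~0.10 of theta
between the two homozygous clusters of a DH population; DBSCAN at cluster
distance 0.07 merges them, the reachability-profile cut at the forced
two-cluster threshold separates them again.
"""

import numpy as np

from polyclust.calling import ProtocolParams, _scaled_coords
from polyclust.cluster_core import PointSet, dbscan, extract_k_clusters, optics
from polyclust.evaluate import split_accuracy
from polyclust.scenarios import compressed_pair_panel

panel, truth = compressed_pair_panel(seed=1, n_markers=1, n_samples=100)
marker = panel.markers[0]
theta, r, samples = panel.marker_points(marker)
params = ProtocolParams()
points = PointSet(np.column_stack([theta, params.r_axis_weight * _scaled_coords(r)]))

merged = dbscan(points, params.step1)
print(f"DBSCAN(0.07, 10) finds {merged.n_clusters} cluster(s) — compression merged them")

profile = optics(points, params.step2)
forced = extract_k_clusters(profile, 2, params.step2)
config = truth.marker(marker).loc[samples, "config"].to_numpy()
acc = split_accuracy(forced.labels, config)
sizes = forced.sizes()
print(f"forced k=2 extraction: clusters of {sizes[1]} and {sizes[2]} points")
print(f"sample-level agreement with the generating split: {acc:.3f}")
print(
    "The cut threshold sits at the reachability dip between the two dosage "
    "configurations, recovering the split DBSCAN could not see."
)
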