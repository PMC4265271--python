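"""In-memory container for two-channel SNP-array intensity data.

An Infinium-style assay reads each (marker, sample) cell as two fluorescence
channels, conventionally summarised in polar form: ``theta`` is the normalised
angle of deviation from the pure first-allele signal (0 = pure A-channel
signal, 1 = pure B-channel signal) and ``R`` is the total hybridisation
intensity (sum of the two channels).  :class:`IntensityPanel` holds the two
marker x sample matrices keyed by marker and sample name, plus per-sample
metadata (population membership, parent flags) used by the bi-parental
resolution workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["IntensityPanel", "theta_r_from_xy"]


def theta_r_from_xy(x, y):
    """Convert raw channel intensities to polar (theta, R).

    theta = (2/pi) * arctan2(y, x), so theta is 1 when x = 0 and 0 when
    y = 0; R = x + y.  Vectorised; accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    theta = (2.0 / np.pi) * np.arctan2(y, x)
    r = x + y
    return theta, r


@dataclass
class IntensityPanel:
    """theta/R matrices (markers x samples) plus sample metadata.

    ``theta`` and ``r`` are :class:`pandas.DataFrame` with identical index
    (marker names) and columns (sample names).  Missing intensities are NaN,
    never silently zero.  ``samples`` is a DataFrame indexed by sample name
    with at least a ``population`` column.
    """

    theta: pd.DataFrame
    r: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.theta.index.equals(self.r.index) or not self.theta.columns.equals(
            self.r.columns
        ):
            raise ValueError("theta and R matrices must share index and columns")
        finite = self.theta.to_numpy()
        bad = (finite < -1e-9) | (finite > 1 + 1e-9)
        if np.any(bad & ~np.isnan(finite)):
            raise ValueError("theta values outside [0, 1]")
        if np.any((self.r.to_numpy() < -1e-9) & ~np.isnan(self.r.to_numpy())):
            raise ValueError("negative R intensity")
        if self.samples is None:
            self.samples = pd.DataFrame(
                {"population": ["all"] * self.theta.shape[1]},
                index=self.theta.columns,
            )
        missing = self.theta.columns.difference(self.samples.index)
        if len(missing):
            raise ValueError(f"samples metadata missing entries: {list(missing)[:5]}")
        if "population" not in self.samples.columns:
            raise ValueError("sample metadata requires a 'population' column")

    # -- convenience accessors -------------------------------------------------
    @property
    def markers(self) -> pd.Index:
        return self.theta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.theta.columns

    @property
    def n_markers(self) -> int:
        return self.theta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.theta.shape[1]

    def populations(self) -> list[str]:
        return sorted(self.samples["population"].unique())

    def marker_points(self, marker: str) -> tuple[np.ndarray, np.ndarray, pd.Index]:
        """Return (theta, r, sample index) for one marker, NaN rows dropped."""
        th = self.theta.loc[marker]
        rr = self.r.loc[marker]
        keep = th.notna() & rr.notna()
        return th[keep].to_numpy(float), rr[keep].to_numpy(float), th.index[keep]

    def subset_samples(self, sample_ids) -> "IntensityPanel":
        ids = pd.Index(sample_ids)
        return IntensityPanel(
            theta=self.theta.loc[:, ids].copy(),
            r=self.r.loc[:, ids].copy(),
            samples=self.samples.loc[ids].copy(),
        )

    @classmethod
    def from_xy(cls, x: pd.DataFrame, y: pd.DataFrame, samples: pd.DataFrame | None = None):
        theta, r = theta_r_from_xy(x.to_numpy(float), y.to_numpy(float))
        return cls(
            theta=pd.DataFrame(theta, index=x.index, columns=x.columns),
            r=pd.DataFrame(r, index=x.index, columns=x.columns),
            samples=samples,
        )
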