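"""ROI-level functional connectivity from channel-wise ΔHbO.

The 48 measurement channels map onto 10 cortical regions of interest
(prefrontal, primary somatosensory, primary motor, premotor/supplementary
motor, and visual cortex; left/right). Each ROI time series is the
arithmetic mean of its member channels' ΔHbO (bad channels excluded), and
the 10x10 functional-connectivity matrix holds Fisher-z-transformed Pearson
correlations with negative correlations zeroed before the transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .fnirs_preprocess import HemoRecording

__all__ = [
    "ROI_ORDER",
    "ChannelMap",
    "RoiSeries",
    "FcMatrix",
    "default_channel_map",
    "load_channel_map",
    "roi_average",
    "connectivity_matrix",
    "fc_to_frame",
]

#: Fixed ROI ordering used for every matrix, curve and nodal-metric output.
ROI_ORDER = ("L_PFC", "R_PFC", "L_S1", "R_S1", "L_M1", "R_M1",
             "L_PMC", "R_PMC", "L_V", "R_V")

#: Clip for sample correlations before atanh, keeping z finite for
#: (near-)duplicate series.
R_CLIP = 0.999999


@dataclass(frozen=True)
class ChannelMap:
    """Channel id (1-based) -> ROI label (one of :data:`ROI_ORDER`)."""

    assignment: dict

    def __post_init__(self):
        assign = dict(self.assignment)
        object.__setattr__(self, "assignment", assign)
        if len(assign) != 48:
            raise ValueError(f"expected 48 mapped channels, got {len(assign)}")
        unknown = set(assign.values()) - set(ROI_ORDER)
        if unknown:
            raise ValueError(f"unknown ROI label(s): {sorted(unknown)}")

    def channels_of(self, roi: str) -> list[int]:
        return sorted(ch for ch, r in self.assignment.items() if r == roi)

    def roi_counts(self) -> dict:
        return {roi: len(self.channels_of(roi)) for roi in ROI_ORDER}


def load_channel_map(path) -> ChannelMap:
    df = pd.read_csv(path)
    assign = {int(row.channel): f"{row.hemisphere}_{row.region}"
              for row in df.itertuples()}
    return ChannelMap(assignment=assign)


def default_channel_map() -> ChannelMap:
    """The probe's channel->ROI assignment shipped with the package."""
    with resources.files("swaynet.data").joinpath("channel_map.csv").open() as fh:
        df = pd.read_csv(fh)
    assign = {int(row.channel): f"{row.hemisphere}_{row.region}"
              for row in df.itertuples()}
    return ChannelMap(assignment=assign)


@dataclass(frozen=True)
class RoiSeries:
    """10 x time ΔHbO matrix, rows in :data:`ROI_ORDER` order."""

    data: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        if d.ndim != 2 or d.shape[0] != len(ROI_ORDER):
            raise ValueError(f"RoiSeries needs {len(ROI_ORDER)} rows")
        if not np.isfinite(d).all():
            raise ValueError("RoiSeries must be finite")


@dataclass(frozen=True)
class FcMatrix:
    """Symmetric non-negative 10x10 Fisher-z connectivity, zero diagonal."""

    z: np.ndarray

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "z", z)
        n = len(ROI_ORDER)
        if z.shape != (n, n):
            raise ValueError(f"FcMatrix must be {n}x{n}")
        if not np.isfinite(z).all():
            raise ValueError("FcMatrix must be finite")
        if (z < 0).any() or not np.allclose(z, z.T) or np.abs(np.diag(z)).max() > 0:
            raise ValueError("FcMatrix must be symmetric, non-negative, "
                             "with zero diagonal")


def roi_average(hemo: HemoRecording, cmap: ChannelMap) -> RoiSeries:
    """Average member channels' ΔHbO per ROI, excluding bad channels.

    Channel ids in the map are 1-based; row ``i`` of ``hemo.hbo`` is channel
    ``i+1``.
    """
    rows = []
    for roi in ROI_ORDER:
        chans = [ch for ch in cmap.channels_of(roi)
                 if (ch - 1) not in hemo.bad_channels]
        if not chans:
            raise ValueError(f"ROI {roi} has no usable channels "
                             "(all excluded as bad)")
        idx = [ch - 1 for ch in chans]
        rows.append(hemo.hbo[idx].mean(axis=0))
    return RoiSeries(data=np.vstack(rows), sampling_rate=hemo.sampling_rate)


def connectivity_matrix(roi: RoiSeries) -> FcMatrix:
    """Pairwise Pearson r -> zero negatives -> Fisher z; symmetric, diag 0."""
    x = roi.data
    if x.shape[1] < 3:
        raise ValueError("need at least 3 time points for correlations")
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = [ROI_ORDER[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant ROI series: {bad}")
    r = np.corrcoef(x)
    r = np.clip(r, 0.0, R_CLIP)  # zero negatives, keep atanh finite
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # exact symmetry against float noise
    np.fill_diagonal(z, 0.0)
    return FcMatrix(z=z)


def fc_to_frame(fc: FcMatrix) -> pd.DataFrame:
    return pd.DataFrame(fc.z, index=list(ROI_ORDER), columns=list(ROI_ORDER))
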