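"""Voxel-intrinsic activation coding and the scalar polarity metric.

Each voxel's BOLD time series is individually z-scored into an intrinsic
activation profile (IAP), then discretized into intrinsic activation levels
(IALs) over the alphabet {-1, 0, +1} = {Low, Neutral, High}.  From the IAL
matrix we compute, per TR, the proportions ``h(t)``, ``l(t)``, ``n(t)`` of
voxels at each level, and the polarity metric

    Pi(t) = -(h_z(t) * l_z(t))

where ``h_z`` and ``l_z`` are the z-scored proportion time series.  Pi is
large and positive when one of h, l is far above 1/3 while the other is far
below (a polarized brain), near zero when the brain is balanced, and
negative when h and l deviate in the same direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import MaskedVolumeSeries

#: Standard-normal quantile at 2/3 — the tercile cut on z-scored voxel series.
#: Carried at full precision; prints as 0.43 at two decimals.
TERCILE_Z = float(stats.norm.ppf(2.0 / 3.0))

DISCRETIZATION_MODES = ("gaussian_threshold", "empirical_tercile")


@dataclass
class IALMatrix:
    """Discretized intrinsic activation levels, one row per voxel.

    ``levels`` is a V x T int8 matrix over {-1, 0, +1}.  ``thresholds`` are
    the (low, high) cut points actually used; in ``empirical_tercile`` mode
    they are per-voxel and the stored pair is the population median cut.
    """

    levels: np.ndarray
    mode: str
    thresholds: tuple[float, float]

    @property
    def n_voxels(self) -> int:
        return self.levels.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.levels.shape[1]


@dataclass
class PolarityProportions:
    """Per-TR proportions of voxels at each intrinsic activation level."""

    h: np.ndarray
    l: np.ndarray
    n: np.ndarray
    pi_metric: np.ndarray | None = field(default=None)

    def stacked(self) -> np.ndarray:
        """T x 3 array of (h, l, n) rows, the clustering features for dPRs."""
        return np.column_stack([self.h, self.l, self.n])


def zscore_voxels(series: MaskedVolumeSeries) -> MaskedVolumeSeries:
    """Z-score each voxel's time series (sample SD, ddof=1).

    Raises if any row has zero variance; such voxels should have been
    excluded at load time.
    """
    data = series.data
    sd = data.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"zero-variance voxel(s) at row index {bad[:5].tolist()}"
            f"{'...' if bad.size > 5 else ''}; exclude before z-scoring"
        )
    z = (data - data.mean(axis=1, keepdims=True)) / sd[:, None]
    return MaskedVolumeSeries(
        data=z,
        coords=series.coords,
        grid_shape=series.grid_shape,
        affine=series.affine,
        tr_seconds=series.tr_seconds,
    )


def discretize_ial(
    series: MaskedVolumeSeries, mode: str = "gaussian_threshold"
) -> IALMatrix:
    """Discretize z-scored voxel series into {-1, 0, +1} activation levels.

    ``gaussian_threshold`` cuts every voxel at +/- Phi^{-1}(2/3) ~ +/-0.431,
    the terciles of the standard normal; values exactly at a cut point are
    assigned to the Neutral band.  ``empirical_tercile`` uses each voxel's
    own empirical terciles (via ranks) so that per-voxel level counts are
    equal to within one sample — the reading under which every voxel spends
    exactly a third of its time at each level.
    """
    if mode not in DISCRETIZATION_MODES:
        raise ValueError(f"unknown discretization mode {mode!r}")
    data = series.data
    V, T = data.shape
    levels = np.zeros((V, T), dtype=np.int8)
    if mode == "gaussian_threshold":
        levels[data > TERCILE_Z] = 1
        levels[data < -TERCILE_Z] = -1
        thresholds = (-TERCILE_Z, TERCILE_Z)
    else:
        # rank-based terciles: stable argsort, ties broken by time order
        i1 = int(round(T / 3.0))
        i2 = int(round(2.0 * T / 3.0))
        ranks = np.argsort(np.argsort(data, axis=1, kind="stable"), axis=1)
        levels[ranks < i1] = -1
        levels[ranks >= i2] = 1
        sorted_data = np.sort(data, axis=1)
        thresholds = (
            float(np.median(sorted_data[:, i1 - 1])),
            float(np.median(sorted_data[:, i2])),
        )
    return IALMatrix(levels=levels, mode=mode, thresholds=thresholds)


def polarity_proportions(ial: IALMatrix) -> PolarityProportions:
    """Per-TR fractions of voxels at High (+1), Low (-1) and Neutral (0)."""
    V = ial.n_voxels
    if V < 1:
        raise ValueError("need at least one voxel")
    lv = ial.levels
    h = (lv == 1).sum(axis=0) / V
    l = (lv == -1).sum(axis=0) / V
    n = (lv == 0).sum(axis=0) / V
    return PolarityProportions(h=h, l=l, n=n)


def polarity_metric(props: PolarityProportions) -> np.ndarray:
    """Scalar polarity index Pi(t) = -(h_z(t) * l_z(t)).

    z-scoring is per subject over that subject's own scan, with population
    SD (ddof=0) so that the scan mean of Pi equals -corr(h, l) exactly — a
    convenient testable identity.  The result is attached to ``props`` as
    ``pi_metric`` and also returned.
    """
    h, l = props.h, props.l
    if h.size < 3:
        raise ValueError("need at least 3 TRs to z-score proportions")
    if np.ptp(h) == 0 or np.ptp(l) == 0:
        raise ValueError("constant h or l series: polarity metric undefined")
    hz = (h - h.mean()) / h.std()
    lz = (l - l.mean()) / l.std()
    pi = -(hz * lz)
    props.pi_metric = pi
    return pi
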