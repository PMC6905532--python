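"""Co-polarization patterns (CoPPs): clustered polarity-coded brain volumes.

Every TR's whole-brain IAL vector (V entries in {-1, 0, +1}) is a sample;
k-means over all subjects and TRs (k = 13 at study scale) yields centroids
in [-1, 1]^V — the CoPPs.  A CoPP is "strongly polarized" when the mean of
its centroid entries is extreme under a deliberately conservative Gaussian
null: treating all of a subject's TRs as one dependent observation and the
brain as containing only ``n_independent_units`` (default 47, the number of
independent spatial networks) independent units of space, the null for the
centroid grand mean mu_i is

    mu_i ~ N(0, 1 / (n_units * n_i)),    n_i = n_subjects * r_i

with r_i the population occupancy rate of cluster i.  The alpha = 0.001
tail of this distribution gives the magnitude cut; the sign of mu_i then
labels the CoPP positively or negatively polarized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .polarity import IALMatrix
from .regimes import StateModel, _occupancy, _run_kmeans, _split


@dataclass
class CoppModel(StateModel):
    """StateModel over IAL volumes, with the polarization-test bookkeeping."""

    centroid_means: np.ndarray = field(default=None)            # (k,) mu_CoPP
    occupancy_rates_population: np.ndarray = field(default=None)  # (k,) r_i
    effective_n: np.ndarray = field(default=None)               # (k,) n_i
    polarity_class: list | None = None


def fit_copps(
    ial_per_subject: Sequence[IALMatrix | np.ndarray],
    k: int = 13,
    seed: int = 0,
    replicates: int = 20,
) -> CoppModel:
    """Cluster polarity-coded volumes from all subjects and TRs.

    Each subject contributes T samples (the columns of its V x T IAL
    matrix).  Samples are kept int8 until k-means; centroids are float64
    per-voxel means in [-1, 1].
    """
    stacks = []
    for item in ial_per_subject:
        levels = item.levels if isinstance(item, IALMatrix) else np.asarray(item)
        if not np.all(np.isin(levels, (-1, 0, 1))):
            raise ValueError("IAL entries must lie in {-1, 0, +1}")
        stacks.append(levels.T.astype(np.int8))    # (T, V)
    lengths = [s.shape[0] for s in stacks]
    samples = np.vstack(stacks)
    km = _run_kmeans(samples.astype(np.float64), k, seed, replicates)
    labels = _split(km.labels_, lengths)
    occupancy = _occupancy(labels, k)
    r_i = np.bincount(km.labels_, minlength=k) / samples.shape[0]
    n_subjects = len(lengths)
    return CoppModel(
        centroids=km.cluster_centers_,
        labels=labels,
        occupancy=occupancy,
        k=k,
        seed=seed,
        state_names=[f"CoPP-{i}" for i in range(k)],
        centroid_means=km.cluster_centers_.mean(axis=1),
        occupancy_rates_population=r_i,
        effective_n=n_subjects * r_i,
    )


def polarization_threshold(
    n_i: float,
    n_independent_units: int = 47,
    alpha: float = 0.001,
    tail: str = "each",
) -> float:
    """Magnitude cut on |mu_CoPP| from the conservative Gaussian null.

    Returns ``z* * sqrt(1 / (n_units * n_i))`` where z* is the
    standard-normal quantile at 1 - alpha (``tail='each'``, alpha mass in
    each tail — the default) or 1 - alpha/2 (``tail='total'``).
    """
    if n_i <= 0:
        raise ValueError(f"effective sample size must be positive, got {n_i}")
    if tail == "each":
        zstar = stats.norm.ppf(1.0 - alpha)
    elif tail == "total":
        zstar = stats.norm.ppf(1.0 - alpha / 2.0)
    else:
        raise ValueError(f"unknown tail convention {tail!r}")
    return float(zstar * np.sqrt(1.0 / (n_independent_units * n_i)))


def naive_null_scale(n_voxels: int, cluster_count: float) -> float:
    """Rescaling factor v * c_i of the un-shrunk (independence) null.

    Under full independence the centroid grand mean would be
    N(0, 1/(v * c_i)); at whole-brain scale this factor exceeds 1e7, so the
    conservative effective-n null above is used instead.
    """
    return float(n_voxels * cluster_count)


def classify_copps(
    model: CoppModel,
    alpha: float = 0.001,
    n_independent_units: int = 47,
    tail: str = "each",
) -> list[str]:
    """Label each CoPP positive / negative / neutral by the tail test.

    Centroid i is ``positive`` if mu_i exceeds its threshold, ``negative``
    if mu_i < -threshold, else ``neutral``.  The classification is stored
    on the model and returned.
    """
    classes = []
    for mu, n_i in zip(model.centroid_means, model.effective_n):
        if n_i <= 0:
            # unoccupied cluster: no samples, nothing to test
            classes.append("neutral")
            continue
        thr = polarization_threshold(n_i, n_independent_units, alpha, tail)
        if mu > thr:
            classes.append("positive")
        elif mu < -thr:
            classes.append("negative")
        else:
            classes.append("neutral")
    model.polarity_class = classes
    return classes
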