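"""Dynamic polarity regimes: k-means over per-TR (h, l, n) proportion vectors.

Pooling the length-3 proportion vectors of every subject and TR and
clustering with k = 3 yields three stylized whole-brain regimes:
Polarized-High (h >> 1/3), Polarized-Low (l >> 1/3) and a Non-Polarized /
balanced regime (h ~ l ~ n ~ 1/3).  Clusters are relabeled canonically so
that state 0 is always Polarized-High, state 1 Polarized-Low and state 2
Non-Polarized, independent of k-means initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

#: canonical dPR state indices after relabeling
POLARIZED_HIGH, POLARIZED_LOW, NON_POLARIZED = 0, 1, 2
POLARIZED_STATES = (POLARIZED_HIGH, POLARIZED_LOW)

DPR_STATE_NAMES = ["Polarized-High", "Polarized-Low", "Non-Polarized"]


@dataclass
class StateModel:
    """A fitted clustering of per-sample feature vectors into k states.

    Reused across the pipeline: dPRs (k=3 on T x 3 proportion vectors),
    participation-map clusters (k=2 on V-vectors), co-polarization patterns
    (k=13 on V-vectors) and dFNC states (k=5 on correlation vectors).
    """

    centroids: np.ndarray            # (k, d)
    labels: list                     # per-subject integer label arrays
    occupancy: np.ndarray            # (n_subjects, k), rows sum to 1
    k: int
    seed: int
    state_names: list | None = None
    inertia_curve: list | None = field(default=None)


def _pool(samples_per_subject: Sequence[np.ndarray]) -> tuple[np.ndarray, list[int]]:
    arrays = [np.atleast_2d(np.asarray(s, dtype=float)) for s in samples_per_subject]
    lengths = [a.shape[0] for a in arrays]
    return np.vstack(arrays), lengths


def _split(labels: np.ndarray, lengths: list[int]) -> list[np.ndarray]:
    out, start = [], 0
    for n in lengths:
        out.append(labels[start : start + n].copy())
        start += n
    return out


def _occupancy(labels: list[np.ndarray], k: int) -> np.ndarray:
    occ = np.zeros((len(labels), k))
    for i, lab in enumerate(labels):
        occ[i] = np.bincount(lab, minlength=k) / len(lab)
    return occ


def _run_kmeans(
    samples: np.ndarray, k: int, seed: int, replicates: int
) -> KMeans:
    if samples.shape[0] < k:
        raise ValueError(f"need at least k={k} samples, got {samples.shape[0]}")
    if np.allclose(samples, samples[0]):
        raise ValueError("degenerate data: all samples identical")
    km = KMeans(
        n_clusters=k,
        n_init=replicates,
        max_iter=3000,
        random_state=seed,
    )
    km.fit(samples)
    return km


def canonical_dpr_order(centroids: np.ndarray) -> list[int]:
    """Order cluster indices as [Polarized-High, Polarized-Low, rest...].

    High = argmax of the h component (column 0), Low = argmax of the l
    component (column 1) among the remaining clusters; further clusters keep
    their original order.  Ties resolve to the lowest original index (the
    numpy argmax convention).
    """
    k = centroids.shape[0]
    high = int(np.argmax(centroids[:, 0]))
    rest = [i for i in range(k) if i != high]
    if not rest:
        return [high]
    low = rest[int(np.argmax(centroids[rest, 1]))]
    others = [i for i in rest if i != low]
    return [high, low, *others]


def fit_dpr(
    props_per_subject: Sequence[np.ndarray],
    k: int = 3,
    seed: int = 0,
    replicates: int = 50,
) -> StateModel:
    """Cluster pooled (h, l, n) vectors into k dynamic polarity regimes.

    Parameters
    ----------
    props_per_subject
        One T x 3 array per subject (``PolarityProportions.stacked()``).
    replicates
        Number of k-means restarts; the best-inertia solution is kept.
    """
    samples, lengths = _pool(props_per_subject)
    km = _run_kmeans(samples, k, seed, replicates)
    order = canonical_dpr_order(km.cluster_centers_) if k >= 2 else [0]
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new
    labels = remap[km.labels_]
    centroids = km.cluster_centers_[order]
    per_subject = _split(labels, lengths)
    names = DPR_STATE_NAMES if k == 3 else [f"state-{i}" for i in range(k)]
    return StateModel(
        centroids=centroids,
        labels=per_subject,
        occupancy=_occupancy(per_subject, k),
        k=k,
        seed=seed,
        state_names=names,
    )


def occupancy_rates(model: StateModel) -> np.ndarray:
    """Per-subject fraction of samples assigned to each state (rows sum to 1)."""
    return _occupancy(model.labels, model.k)


def polarized_occupancy(model: StateModel) -> np.ndarray:
    """Per-subject occupancy of the two polarized dPR states combined."""
    occ = occupancy_rates(model)
    return occ[:, list(POLARIZED_STATES)].sum(axis=1)


def elbow_curve(
    samples: np.ndarray,
    k_range: Sequence[int],
    seed: int = 0,
    replicates: int = 10,
) -> list[tuple[int, float]]:
    """Within-cluster sum of squares for each k in ``k_range``."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range is empty")
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    curve = []
    for k in k_range:
        if k >= samples.shape[0]:
            curve.append((k, 0.0))
            continue
        km = _run_kmeans(samples, k, seed, replicates)
        curve.append((k, float(km.inertia_)))
    return curve
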