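"""Polarity participation maps (PPMs) and their group-level statistics.

A subject's PPM assigns each voxel the proportion of that subject's
polarized whole-brain regimes the voxel actively participated in: TRs
labeled Polarized-High where the voxel's IAL was +1, plus TRs labeled
Polarized-Low where its IAL was -1, divided by the total number of
polarized TRs.  This combined-count form guarantees values in [0, 1].

PPMs are clustered across subjects (k = 2), projected onto z-scored network
spatial maps thresholded at z >= 1.25, and compared between groups with
voxelwise tests under Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .polarity import IALMatrix
from .regimes import (
    POLARIZED_HIGH,
    POLARIZED_LOW,
    StateModel,
    _occupancy,
    _run_kmeans,
)

logger = logging.getLogger("brainpolarity")


@dataclass
class ParticipationMap:
    values: np.ndarray        # (V,), in [0, 1]
    n_polarized_trs: int
    subject_id: str = ""

    @property
    def is_valid(self) -> bool:
        return self.n_polarized_trs > 0


def compute_ppm(
    ial: IALMatrix,
    dpr_labels: np.ndarray,
    high_label: int = POLARIZED_HIGH,
    low_label: int = POLARIZED_LOW,
    subject_id: str = "",
    per_state_denominator: bool = False,
) -> ParticipationMap:
    """Polarity participation map for one subject.

    With the default combined-count denominator,

        PPM(v) = (#{t: label=High, IAL_v(t)=+1}
                  + #{t: label=Low, IAL_v(t)=-1}) / #{t: label in {High, Low}}

    which lies in [0, 1].  ``per_state_denominator=True`` instead sums the
    two per-state proportions (range [0, 2]); exposed for comparison only.

    A subject with zero polarized TRs yields an invalid map
    (``is_valid`` False) that downstream clustering excludes.
    """
    dpr_labels = np.asarray(dpr_labels)
    if dpr_labels.shape[0] != ial.n_timepoints:
        raise ValueError(
            f"label length {dpr_labels.shape[0]} != {ial.n_timepoints} TRs"
        )
    high_t = dpr_labels == high_label
    low_t = dpr_labels == low_label
    n_high, n_low = int(high_t.sum()), int(low_t.sum())
    n_pol = n_high + n_low
    if n_pol == 0:
        logger.warning("subject %r has no polarized TRs; PPM invalid", subject_id)
        return ParticipationMap(
            values=np.zeros(ial.n_voxels), n_polarized_trs=0, subject_id=subject_id
        )
    high_hits = (ial.levels[:, high_t] == 1).sum(axis=1)
    low_hits = (ial.levels[:, low_t] == -1).sum(axis=1)
    if per_state_denominator:
        values = np.zeros(ial.n_voxels)
        if n_high:
            values += high_hits / n_high
        if n_low:
            values += low_hits / n_low
    else:
        values = (high_hits + low_hits) / n_pol
    return ParticipationMap(
        values=values, n_polarized_trs=n_pol, subject_id=subject_id
    )


def cluster_ppms(
    maps: Sequence[ParticipationMap],
    k: int = 2,
    seed: int = 0,
    replicates: int = 50,
) -> StateModel:
    """Cluster subject PPMs into k spatial-profile clusters.

    Invalid maps (no polarized TRs) are excluded.  Clusters are ordered by
    descending mean centroid participation, so cluster 0 is the
    high-participation profile.
    """
    valid = [m for m in maps if m.is_valid]
    if len(valid) < k:
        raise ValueError(f"need at least k={k} valid maps, got {len(valid)}")
    X = np.vstack([m.values for m in valid])
    km = _run_kmeans(X, k, seed, replicates)
    order = list(np.argsort(-km.cluster_centers_.mean(axis=1), kind="stable"))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new
    labels = remap[km.labels_]
    per_subject = [np.array([lab]) for lab in labels]
    return StateModel(
        centroids=km.cluster_centers_[order],
        labels=per_subject,
        occupancy=_occupancy(per_subject, k),
        k=k,
        seed=seed,
        state_names=[f"ppm-cluster-{i + 1}" for i in range(k)],
    )


def network_participation(
    ppm: ParticipationMap,
    network_maps: np.ndarray,
    map_z_threshold: float = 1.25,
) -> np.ndarray:
    """Mean z-scored participation within each network's top voxels.

    Each network spatial map is z-scored over voxels (GICA map scale is
    arbitrary) and thresholded at ``z >= map_z_threshold`` (1.25 retains
    roughly the top decile of a Gaussian-valued map).  The subject's PPM is
    likewise z-scored over voxels, and the mean z-scored participation over
    each network's supra-threshold voxel set is returned — possibly
    negative, meaning sub-mean participation.  Networks with no
    supra-threshold voxels yield NaN (flagged via a log warning).
    """
    network_maps = np.atleast_2d(np.asarray(network_maps, dtype=float))
    if network_maps.shape[1] != ppm.values.shape[0]:
        raise ValueError("network maps are not on the PPM voxel grid")
    sd = ppm.values.std()
    if sd == 0:
        raise ValueError("constant PPM cannot be z-scored")
    ppm_z = (ppm.values - ppm.values.mean()) / sd
    out = np.full(network_maps.shape[0], np.nan)
    for i, m in enumerate(network_maps):
        msd = m.std()
        if msd == 0:
            logger.warning("network %d map is constant; participation undefined", i)
            continue
        mz = (m - m.mean()) / msd
        sel = mz >= map_z_threshold
        if not sel.any():
            logger.warning("network %d has no supra-threshold voxels", i)
            continue
        out[i] = ppm_z[sel].mean()
    return out


def _ols_tstats(Y: np.ndarray, X: np.ndarray, col: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-column OLS t-statistic and two-sided p for one design column.

    Y is (n, V); X is (n, p).  Vectorized across the V responses.
    """
    from scipy import stats as sps

    n, p = X.shape
    if n <= p:
        raise ValueError("more regressors than observations")
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < p:
        raise ValueError("singular design matrix")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ X.T @ Y                       # (p, V)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[col, col])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[col] / se
    t = np.where(se == 0, 0.0, t)
    pvals = 2 * sps.t.sf(np.abs(t), dof)
    return t, pvals


def voxelwise_group_difference(
    maps: Sequence[ParticipationMap],
    groups: Sequence | None = None,
    covariates: np.ndarray | None = None,
    contrast: str = "group",
    q: float = 0.05,
) -> dict:
    """Voxelwise t-statistic map with BH-FDR mask.

    contrast="mean": one-sample t-test per voxel of participation against
    the grand mean participation over all voxels and subjects.
    contrast="group": t for a binary group indicator in a per-voxel OLS fit
    with optional nuisance covariates.

    Returns a dict with ``t``, ``p``, ``fdr_mask`` (BH at ``q``) and the
    degrees of freedom.
    """
    valid = [m for m in maps if m.is_valid]
    Y = np.vstack([m.values for m in valid])          # (n, V)
    if np.ptp(Y) == 0:
        raise ValueError("constant participation maps: no variance to test")
    n = Y.shape[0]
    if contrast == "mean":
        grand = Y.mean()
        X = np.ones((n, 1))
        t, p = _ols_tstats(Y - grand, X, col=0)
        dof = n - 1
    elif contrast == "group":
        if groups is None:
            raise ValueError("contrast='group' requires group labels")
        g = np.asarray(groups)[: n]
        codes = (g == np.unique(g)[-1]).astype(float)
        cols = [np.ones(n), codes]
        if covariates is not None:
            cov = np.atleast_2d(np.asarray(covariates, dtype=float))
            if cov.shape[0] != n:
                cov = cov.T
            cols.extend(cov.T)
        X = np.column_stack(cols)
        if min(np.bincount(codes.astype(int))) < 2:
            raise ValueError("need at least 2 subjects per group")
        t, p = _ols_tstats(Y, X, col=1)
        dof = n - X.shape[1]
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    finite = np.isfinite(p)
    mask = np.zeros_like(p, dtype=bool)
    if finite.any():
        mask[finite] = multipletests(p[finite], alpha=q, method="fdr_bh")[0]
    return {"t": t, "p": p, "fdr_mask": mask, "dof": dof}
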