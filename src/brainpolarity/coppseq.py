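"""Channel encoding of CoPP label sequences and dictionary contributions.

A CoPP occupancy sequence is symbolic — the integer labels carry no
numerical meaning — so it is recoded as a K-channel binary time series with
exactly one active channel per timestep.  Given an externally learned
convolutional dictionary (K-channel kernels of common width, typically 7
TRs) and nonnegative per-element activation series, this module computes
the additive reconstruction, its error, and per-element contribution
totals, then tests group effects on contributions element-by-element under
FDR control.  Dictionary learning itself (convolutional basis pursuit
denoising) is delegated to external solvers and is not reimplemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import nuisance_regression
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("brainpolarity")


@dataclass
class ChannelSeries:
    """K x T one-hot binary encoding of a length-T symbolic sequence."""

    channels: np.ndarray
    state_index_map: list

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.channels.shape[1]


def encode_channels(labels: np.ndarray, k: int) -> ChannelSeries:
    """One-hot encode a state-label sequence into k binary channels."""
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() >= k):
        raise ValueError(
            f"labels must lie in [0, {k}); found range "
            f"[{labels.min()}, {labels.max()}]"
        )
    channels = np.zeros((k, labels.size), dtype=np.int8)
    channels[labels, np.arange(labels.size)] = 1
    return ChannelSeries(channels=channels, state_index_map=list(range(k)))


def decode_channels(series: ChannelSeries) -> np.ndarray:
    """Inverse of :func:`encode_channels`."""
    if not np.all(series.channels.sum(axis=0) == 1):
        raise ValueError("not a valid one-hot channel series")
    return np.asarray(series.state_index_map)[np.argmax(series.channels, axis=0)]


def element_contributions(
    series: ChannelSeries,
    dictionary: np.ndarray,
    coefficients: np.ndarray,
) -> dict:
    """Per-element contribution totals and the additive reconstruction.

    Parameters
    ----------
    dictionary : ndarray, shape (E, K, w)
        E multichannel kernels of common temporal width w.
    coefficients : ndarray, shape (E, T)
        Nonnegative activation series, one per element, aligned with the
        input; treated as given (produced by an external sparse solver).

    Returns a dict with ``totals`` (sum over time of each element's
    activations), ``reconstruction`` (K x T, sum of kernel (*) coefficient
    over elements, truncated to T) and ``error`` (Frobenius norm of the
    reconstruction residual).
    """
    dictionary = np.asarray(dictionary, dtype=float)
    coefficients = np.asarray(coefficients, dtype=float)
    if dictionary.ndim != 3:
        raise ValueError("dictionary must be (n_elements, n_channels, width)")
    E, K, w = dictionary.shape
    if K != series.n_channels:
        raise ValueError(
            f"dictionary has {K} channels but the series has {series.n_channels}"
        )
    T = series.n_timepoints
    if coefficients.shape != (E, T):
        raise ValueError(
            f"coefficients must be ({E}, {T}), got {coefficients.shape}"
        )
    if (coefficients < 0).any():
        raise ValueError("activation coefficients must be nonnegative")
    recon = np.zeros((K, T))
    for e in range(E):
        for c in range(K):
            recon[c] += np.convolve(coefficients[e], dictionary[e, c])[:T]
    totals = coefficients.sum(axis=1)
    error = float(np.linalg.norm(series.channels - recon))
    return {"totals": totals, "reconstruction": recon, "error": error}


def contribution_group_effect(
    contributions: np.ndarray,
    cohort: pd.DataFrame,
    predictor: str = "group",
    q: float = 0.05,
) -> pd.DataFrame:
    """Nuisance-corrected group effect on each dictionary element.

    ``contributions`` is subjects x elements.  Each element's contribution
    total is regressed on the predictor with age, gender and mean framewise
    displacement as nuisance covariates; p-values are BH-FDR corrected
    across elements.  Constant elements are skipped with a warning.
    """
    contributions = np.atleast_2d(np.asarray(contributions, dtype=float))
    rows = []
    for e in range(contributions.shape[1]):
        y = contributions[:, e]
        if np.ptp(y) == 0:
            logger.warning("element %d has constant contributions; skipped", e)
            rows.append({"element": e, "beta": np.nan, "p": np.nan})
            continue
        res = nuisance_regression(y, predictor=predictor, cohort=cohort)
        rows.append({"element": e, "beta": res["beta"], "p": res["p"]})
    table = pd.DataFrame(rows)
    finite = table["p"].notna()
    table["fdr_sig"] = False
    if finite.any():
        table.loc[finite, "fdr_sig"] = multipletests(
            table.loc[finite, "p"], alpha=q, method="fdr_bh"
        )[0]
    return table
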