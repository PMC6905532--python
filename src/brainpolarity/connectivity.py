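"""Network connectivity estimation and the polarity-connectivity statistics.

Covers the standard dynamic functional network connectivity (dFNC)
machinery — zero-phase Butterworth band-pass of network timecourses into
[0.05, 0.15] Hz, sliding tapered-rectangular windows of 22 TRs advanced 1
TR at a time with weighted Pearson correlations, k-means connectivity
states — plus the statistical layer: polarized-regime occupancy within
windows of each dFNC state, nuisance-corrected regressions (age, gender,
motion), and the FNC mediation comparison in which group effects on
connectivity are re-estimated with polarized-regime occupancy as a
covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .regimes import POLARIZED_STATES, StateModel, _occupancy, _run_kmeans, _split

logger = logging.getLogger("brainpolarity")

DEFAULT_COVARIATES = ("age", "gender", "mean_fd")
SYMPTOM_COLUMNS = ("sympt_pos", "sympt_neg", "sympt_gen")


@dataclass
class WindowedConnectivity:
    """Sliding-window pairwise correlations for one subject."""

    windows: np.ndarray          # (n_windows, n_pairs)
    starts: np.ndarray           # (n_windows,) first TR of each window
    window_length: int
    taper: str
    pair_index: list             # list of (i, j) network pairs, i < j

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


def bandpass_timecourses(
    tcs: np.ndarray,
    tr_seconds: float = 2.0,
    low_hz: float = 0.05,
    high_hz: float = 0.15,
    order: int = 5,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of network timecourses.

    ``tcs`` is networks x T; filtering is forward-backward (filtfilt) along
    the time axis, so the pass band is phase-neutral and the effective
    attenuation is twice the one-pass filter order.
    """
    tcs = np.atleast_2d(np.asarray(tcs, dtype=float))
    nyquist = 0.5 / tr_seconds
    if not 0 < low_hz < high_hz < nyquist:
        raise ValueError(
            f"band edges ({low_hz}, {high_hz}) Hz must satisfy "
            f"0 < low < high < Nyquist ({nyquist} Hz)"
        )
    if tcs.shape[1] <= 3 * order:
        raise ValueError(f"need more than {3 * order} timepoints to filter")
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds, output="sos"
    )
    return signal.sosfiltfilt(sos, tcs, axis=1)


def tapered_window(length: int = 22, gaussian_sd: float = 3.0) -> np.ndarray:
    """Rectangular window convolved with a Gaussian (sigma in TRs).

    The convention of the dFNC literature for the "tapered rectangular"
    window; normalized to unit sum for use as correlation weights.
    """
    rect = np.ones(length)
    half = int(np.ceil(4 * gaussian_sd))
    x = np.arange(-half, half + 1)
    g = np.exp(-0.5 * (x / gaussian_sd) ** 2)
    full = np.convolve(rect, g / g.sum(), mode="full")
    start = (full.size - length) // 2
    w = full[start : start + length]
    return w / w.sum()


def _weighted_corr(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation matrix of rows of X (networks x T)."""
    w = w / w.sum()
    mean = X @ w
    Xc = X - mean[:, None]
    cov = (Xc * w) @ Xc.T
    sd = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    return corr


def sliding_window_fnc(
    tcs: np.ndarray,
    window_length: int = 22,
    taper: str | np.ndarray = "tapered",
    gaussian_sd: float = 3.0,
) -> WindowedConnectivity:
    """Windowed pairwise correlations, windows advanced 1 TR at a time.

    ``taper`` may be "tapered" (rectangular-convolved-Gaussian, the
    default), "rect" (untapered), or an explicit weight vector of the
    window length.  A network that is constant within a window yields NaN
    correlations for its pairs in that window (logged once).
    """
    tcs = np.atleast_2d(np.asarray(tcs, dtype=float))
    N, T = tcs.shape
    if T < window_length:
        raise ValueError(f"scan of {T} TRs is shorter than the {window_length}-TR window")
    if isinstance(taper, str):
        if taper == "tapered":
            w = tapered_window(window_length, gaussian_sd)
        elif taper == "rect":
            w = np.ones(window_length) / window_length
        else:
            raise ValueError(f"unknown taper {taper!r}")
        taper_name = taper
    else:
        w = np.asarray(taper, dtype=float)
        if w.shape[0] != window_length:
            raise ValueError("taper length must equal window_length")
        taper_name = "custom"
    iu = np.triu_indices(N, k=1)
    pair_index = list(zip(iu[0].tolist(), iu[1].tolist()))
    n_windows = T - window_length + 1
    out = np.empty((n_windows, len(pair_index)))
    warned = False
    for s in range(n_windows):
        seg = tcs[:, s : s + window_length]
        corr = _weighted_corr(seg, w)
        if not warned and np.isnan(corr[iu]).any():
            logger.warning("constant network within window %d: NaN correlations", s)
            warned = True
        out[s] = corr[iu]
    return WindowedConnectivity(
        windows=out,
        starts=np.arange(n_windows),
        window_length=window_length,
        taper=taper_name,
        pair_index=pair_index,
    )


def static_fnc(tcs: np.ndarray) -> np.ndarray:
    """Scan-length FNC: a single untapered window covering the whole scan."""
    tcs = np.atleast_2d(np.asarray(tcs, dtype=float))
    wc = sliding_window_fnc(tcs, window_length=tcs.shape[1], taper="rect")
    return wc.windows[0]


def fit_dfnc_states(
    windowed: Sequence[WindowedConnectivity],
    k: int = 5,
    seed: int = 0,
    replicates: int = 20,
) -> StateModel:
    """k-means over pooled window correlation vectors -> dFNC states."""
    stacks = [w.windows for w in windowed]
    lengths = [s.shape[0] for s in stacks]
    samples = np.vstack(stacks)
    if np.isnan(samples).any():
        raise ValueError("NaN correlations in windows; clean before clustering")
    km = _run_kmeans(samples, k, seed, replicates)
    labels = _split(km.labels_, lengths)
    return StateModel(
        centroids=km.cluster_centers_,
        labels=labels,
        occupancy=_occupancy(labels, k),
        k=k,
        seed=seed,
        state_names=[f"dFNC-{i}" for i in range(k)],
    )


def window_polarized_occupancy(
    dpr_labels: np.ndarray,
    window_length: int = 22,
    polarized_states: Sequence[int] = POLARIZED_STATES,
) -> np.ndarray:
    """Per-window fraction of TRs spent in a polarized dPR state.

    A window starting at TR s spans TRs [s, s + window_length - 1].
    """
    dpr_labels = np.asarray(dpr_labels)
    pol = np.isin(dpr_labels, polarized_states).astype(float)
    kernel = np.ones(window_length) / window_length
    return np.convolve(pol, kernel, mode="valid")


def dpr_within_dfnc_test(
    dpr_labels_per_subject: Sequence[np.ndarray],
    dfnc_labels_per_subject: Sequence[np.ndarray],
    window_length: int = 22,
    n_states: int | None = None,
    group_mask: Sequence[bool] | None = None,
    polarized_states: Sequence[int] = POLARIZED_STATES,
) -> pd.DataFrame:
    """Two-sample t-test of polarized-dPR occupancy per dFNC state.

    For each subject, every 22-TR window gets a polarized-dPR occupancy
    (fraction of its TRs in a polarized regime).  For each dFNC state, the
    occupancies of the group's windows labeled with that state are compared
    against the occupancies of all the group's windows; a positive t means
    polarization is elevated during that connectivity state.  States with
    no windows in the group are flagged undefined (NaN).
    """
    if group_mask is not None:
        mask = np.asarray(group_mask, dtype=bool)
        dpr_labels_per_subject = [
            s for s, keep in zip(dpr_labels_per_subject, mask) if keep
        ]
        dfnc_labels_per_subject = [
            s for s, keep in zip(dfnc_labels_per_subject, mask) if keep
        ]
    occ_all, lab_all = [], []
    for dpr, dfnc in zip(dpr_labels_per_subject, dfnc_labels_per_subject):
        occ = window_polarized_occupancy(dpr, window_length, polarized_states)
        dfnc = np.asarray(dfnc)
        if occ.shape[0] != dfnc.shape[0]:
            raise ValueError(
                f"{dfnc.shape[0]} window labels vs {occ.shape[0]} windows"
            )
        occ_all.append(occ)
        lab_all.append(dfnc)
    occ_all = np.concatenate(occ_all)
    lab_all = np.concatenate(lab_all)
    if n_states is None:
        n_states = int(lab_all.max()) + 1
    rows = []
    for j in range(n_states):
        in_state = occ_all[lab_all == j]
        if in_state.size == 0:
            logger.warning("dFNC state %d has no windows in this group", j)
            rows.append({"state": j, "t": np.nan, "p": np.nan, "n_windows": 0})
            continue
        if np.ptp(occ_all) == 0:
            # every window has the same occupancy: nothing to distinguish
            rows.append({"state": j, "t": 0.0, "p": 1.0,
                         "n_windows": int(in_state.size)})
            continue
        t, p = stats.ttest_ind(in_state, occ_all)
        rows.append({"state": j, "t": float(t), "p": float(p),
                     "n_windows": int(in_state.size)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regressions


def _encode_gender(col: pd.Series) -> np.ndarray:
    if col.dtype.kind in "if":
        return col.to_numpy(dtype=float)
    return (col.astype(str) == sorted(col.astype(str).unique())[-1]).astype(float).to_numpy()


def _design_column(cohort: pd.DataFrame, name: str, zscore: bool = False) -> np.ndarray:
    if name == "group":
        return (cohort["group"].astype(str) == "SZ").astype(float).to_numpy()
    if name == "gender":
        return _encode_gender(cohort["gender"])
    x = cohort[name].to_numpy(dtype=float)
    if zscore:
        sd = x.std()
        if sd > 0:
            x = (x - x.mean()) / sd
    return x


def nuisance_regression(
    response: np.ndarray,
    predictor: str | np.ndarray,
    cohort: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    extra_covariates: Sequence[str] = (),
    drop_collinear: bool = False,
) -> dict:
    """OLS effect of one predictor with nuisance covariates.

    The predictor of interest is either a cohort column name ("group" is
    coded SZ=1, symptom columns are z-scored) or an explicit array.  Age,
    gender and mean framewise displacement enter as nuisance regressors by
    default; symptom analyses pass the remaining symptom categories via
    ``extra_covariates`` so each category's effect is corrected for the
    others.  Returns the coefficient, two-sided p, t and n.

    A collinear design raises by default.  With ``drop_collinear=True``,
    nuisance covariates that do not add rank (e.g. a covariate confounded
    with the predictor in a small cohort) are dropped with a warning; the
    predictor itself is never dropped.
    """
    y = np.asarray(response, dtype=float)
    if isinstance(predictor, str):
        zsc = predictor in SYMPTOM_COLUMNS
        x = _design_column(cohort, predictor, zscore=zsc)
    else:
        x = np.asarray(predictor, dtype=float)
    def _is_constant(col: np.ndarray) -> bool:
        finite = col[np.isfinite(col)]
        return finite.size == 0 or np.ptp(finite) == 0

    if _is_constant(x):
        raise ValueError("predictor of interest has no variance")
    cols = [x]
    for c in list(covariates) + list(extra_covariates):
        col = _design_column(cohort, c, zscore=c in SYMPTOM_COLUMNS)
        if _is_constant(col):
            # constant covariate is absorbed by the intercept; drop it
            logger.warning("covariate %r is constant; dropped from design", c)
            continue
        cols.append(col)
    X = np.column_stack(cols)
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[keep], X[keep]
    if drop_collinear:
        base = np.column_stack([np.ones(y.size), X[:, 0]])
        kept = [0]
        for j in range(1, X.shape[1]):
            cand = np.column_stack([base, X[:, j]])
            if np.linalg.matrix_rank(cand) == cand.shape[1]:
                base = cand
                kept.append(j)
            else:
                logger.warning("dropping collinear nuisance covariate column %d", j)
        X = X[:, kept]
    if y.size <= X.shape[1] + 1:
        raise ValueError("not enough subjects for the requested regression")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("collinear design matrix")
    fit = sm.OLS(y, Xc).fit()
    return {
        "beta": float(fit.params[1]),
        "p": float(fit.pvalues[1]),
        "t": float(fit.tvalues[1]),
        "n": int(y.size),
    }


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher z-transform of correlations, clipped away from +/-1."""
    return np.arctanh(np.clip(r, -0.999999, 0.999999))


def fnc_effect_table(
    fnc: np.ndarray,
    cohort: pd.DataFrame,
    predictor: str | np.ndarray,
    extra_predictors: dict | None = None,
    q: float = 0.05,
    transform: bool = True,
    drop_collinear: bool = False,
) -> pd.DataFrame:
    """Per-pair regression of FNC on a predictor, with BH-FDR flags.

    ``fnc`` is subjects x pairs of Pearson correlations; Fisher z is applied
    before regression unless ``transform=False``.  ``extra_predictors`` maps
    names to per-subject arrays entered as additional covariates (e.g.
    polarized-regime occupancy in the mediation model).
    """
    fnc = np.atleast_2d(np.asarray(fnc, dtype=float))
    Y = fisher_z(fnc) if transform else fnc
    extra = extra_predictors or {}
    rows = []
    for j in range(Y.shape[1]):
        y = Y[:, j]
        if np.ptp(y[np.isfinite(y)]) == 0:
            rows.append({"pair": j, "beta": np.nan, "p": np.nan})
            continue
        base_cov = list(DEFAULT_COVARIATES)
        res = nuisance_regression(
            y,
            predictor,
            cohort.assign(**{k: v for k, v in extra.items()}),
            covariates=base_cov + list(extra.keys()),
            drop_collinear=drop_collinear,
        )
        rows.append({"pair": j, "beta": res["beta"], "p": res["p"]})
    table = pd.DataFrame(rows)
    finite = table["p"].notna()
    table["fdr_sig"] = False
    if finite.any():
        table.loc[finite, "fdr_sig"] = multipletests(
            table.loc[finite, "p"], alpha=q, method="fdr_bh"
        )[0]
    return table


def fnc_mediation_comparison(
    fnc: np.ndarray,
    cohort: pd.DataFrame,
    polarized_occupancy: np.ndarray,
    q: float = 0.05,
    drop_collinear: bool = False,
) -> dict:
    """Group effects on FNC with and without the polarization covariate.

    Model A regresses each network pair's (Fisher-z) connectivity on group
    plus nuisance covariates; model B additionally includes each subject's
    polarized-regime occupancy.  When group differences in connectivity are
    mediated by polarization, group effects significant in A largely vanish
    in B while occupancy effects persist.  Returns both effect tables, the
    occupancy effect table under model B, and survivor counts.
    """
    occ = np.asarray(polarized_occupancy, dtype=float)
    table_a = fnc_effect_table(fnc, cohort, predictor="group", q=q,
                               drop_collinear=drop_collinear)
    table_b = fnc_effect_table(
        fnc, cohort, predictor="group",
        extra_predictors={"pol_occ": occ}, q=q, drop_collinear=drop_collinear,
    )
    if np.ptp(occ) == 0:
        # no mediator variance: occupancy effects are undefined and model B
        # collapses onto model A
        logger.warning("polarized occupancy is constant; mediator effects undefined")
        table_occ = table_occ_b = None
    else:
        table_occ = fnc_effect_table(fnc, cohort, predictor=occ, q=q,
                                     drop_collinear=drop_collinear)
        sz_code = (cohort["group"].astype(str) == "SZ").astype(float).to_numpy()
        table_occ_b = fnc_effect_table(
            fnc, cohort, predictor=occ, extra_predictors={"sz_code": sz_code},
            q=q, drop_collinear=drop_collinear,
        )
    a_sig = int(table_a["fdr_sig"].sum())
    b_sig = int(table_b["fdr_sig"].sum())
    return {
        "group_only": table_a,
        "group_with_occupancy": table_b,
        "occupancy_only": table_occ,
        "occupancy_with_group": table_occ_b,
        "n_group_sig_without_occupancy": a_sig,
        "n_group_sig_with_occupancy": b_sig,
        "n_group_absorbed": a_sig - b_sig,
    }
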