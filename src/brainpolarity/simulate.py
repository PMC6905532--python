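"""Synthetic rs-fMRI cohorts with built-in whole-brain polarity structure.

No clinical scans ship with this package, so every downstream stage is
exercised on simulated 4D data that carries the statistical structure the
analysis assumes: each subject's voxel time series is

    x_v(t) = gain * s_v * g(t) + network component + white noise

where g(t) is +1 / -1 / 0 while a hidden 3-state semi-Markov regime chain
(geometric dwell times) occupies its High / Low / Neutral state, and
s_v in [0, 1] is a spatially smooth participation field — a few
high-participation blobs on an ellipsoidal gray-matter mask with a central
ventricle-like zero-participation zone.  The regime gain differs by group
(patients get a suppressed gain), which is what makes polarized-regime
occupancy recoverably lower in the patient rows.  Network spatial maps are
approximately disjoint smooth blobs; their timecourses are band-limited to
[0.05, 0.15] Hz at TR = 2 s.

Everything is seeded: the same configuration reproduces the cohort
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import bandpass_timecourses
from .io import MaskedVolumeSeries

GROUPS = ("HC", "SZ")
REGIME_NAMES = ("High", "Low", "Neutral")


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort generator.

    Defaults target desk scale: a 16 x 16 x 8 grid whose ellipsoidal mask
    holds ~1,000 voxels, 160 TRs at TR = 2 s, mean regime dwell of 8 TRs
    and a patient gain at two-thirds of the control gain.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 8)
    n_timepoints: int = 160
    tr_seconds: float = 2.0
    n_hc: int = 4
    n_sz: int = 4
    regime_dwell_mean: float = 8.0
    polarization_gain_hc: float = 1.5
    polarization_gain_sz: float = 0.8
    n_regions: int = 4
    noise_sd: float = 1.0
    network_amplitude: float = 0.5
    n_networks: int = 5
    sz_suppression: bool = True
    confounded_motion: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if self.n_timepoints < 30:
            raise ValueError("need at least 30 timepoints")
        if self.tr_seconds <= 0 or self.noise_sd <= 0 or self.regime_dwell_mean <= 0:
            raise ValueError("tr_seconds, noise_sd and regime_dwell_mean must be positive")
        if self.polarization_gain_hc < 0 or self.polarization_gain_sz < 0:
            raise ValueError("polarization gains must be nonnegative")
        if self.sz_suppression and self.polarization_gain_sz > self.polarization_gain_hc:
            raise ValueError(
                "sz_suppression requires polarization_gain_sz <= polarization_gain_hc"
            )
        if ellipsoid_mask(self.grid_shape).sum() < 100:
            raise ValueError("masked grid volume must be at least 100 voxels")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Parse a plain-text ``key = value`` configuration file."""
        fields = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"cannot parse config line: {line!r}")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            if key == "grid_shape":
                kwargs[key] = tuple(int(v) for v in raw.replace(",", " ").split())
            elif key in ("sz_suppression", "confounded_motion"):
                kwargs[key] = raw.lower() in ("1", "true", "yes", "on")
            elif key in ("n_timepoints", "n_hc", "n_sz", "n_regions", "n_networks", "seed"):
                kwargs[key] = int(raw)
            else:
                kwargs[key] = float(raw)
        return cls(**kwargs)


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    volume: MaskedVolumeSeries
    true_regime_sequence: np.ndarray       # length-T labels in REGIME_NAMES
    true_participation_map: np.ndarray     # (V,) in [0, 1]
    network_timecourses: np.ndarray        # (n_networks, T), band-limited
    metadata_row: dict = field(default_factory=dict)


def ellipsoid_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Binary ellipsoid inscribed in the grid — the synthetic gray matter."""
    idx = np.indices(grid_shape).astype(float)
    center = (np.asarray(grid_shape) - 1) / 2.0
    radii = np.asarray(grid_shape) / 2.0
    d2 = sum(((idx[a] - center[a]) / radii[a]) ** 2 for a in range(3))
    return (d2 <= 1.0).astype(np.uint8)


def _mask_coords(grid_shape: tuple[int, int, int]) -> np.ndarray:
    coords = np.argwhere(ellipsoid_mask(grid_shape) > 0)
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    return coords[order]


def _blob_field(
    coords: np.ndarray, centers: np.ndarray, sigma: float
) -> np.ndarray:
    """Max over Gaussian blobs, evaluated at each masked coordinate."""
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * sigma**2)).max(axis=1)


def _pick_centers(
    coords: np.ndarray, n: int, min_dist: float, rng: np.random.Generator
) -> np.ndarray:
    """Greedy seeded selection of n well-separated centers on the mask."""
    perm = rng.permutation(coords.shape[0])
    chosen: list[np.ndarray] = []
    for i in perm:
        c = coords[i].astype(float)
        if all(np.linalg.norm(c - p) >= min_dist for p in chosen):
            chosen.append(c)
        if len(chosen) == n:
            return np.asarray(chosen)
    raise ValueError(
        f"cannot place {n} blobs with spacing {min_dist:.1f} on this grid"
    )


def participation_field(config: SimulationConfig) -> np.ndarray:
    """Spatially smooth participation field s_v in [0, 1], seeded from config.

    A few high-participation blobs plus a central ventricle-like zone of
    zero participation; shared by all subjects of a cohort.
    """
    coords = _mask_coords(config.grid_shape)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    sigma = max(config.grid_shape) / 6.0
    centers = _pick_centers(coords, config.n_regions, min_dist=1.5 * sigma, rng=rng)
    s = _blob_field(coords, centers, sigma)
    s = s / s.max()
    center = (np.asarray(config.grid_shape) - 1) / 2.0
    ventricle = np.linalg.norm(coords - center, axis=1) < max(config.grid_shape) / 8.0
    s[ventricle] = 0.0
    return s


def generate_network_maps(
    config: SimulationConfig, n_networks: int | None = None
) -> np.ndarray:
    """Approximately disjoint smooth nonnegative network spatial maps.

    Returns an (n_networks, V) stack on the cohort mask.  Raises when the
    requested number of blobs cannot be spaced on the grid.
    """
    n = config.n_networks if n_networks is None else n_networks
    if n < 2:
        raise ValueError("need at least 2 networks")
    coords = _mask_coords(config.grid_shape)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    sigma = max(config.grid_shape) / 9.0
    centers = _pick_centers(coords, n, min_dist=3.0 * sigma, rng=rng)
    maps = np.stack(
        [_blob_field(coords, centers[i : i + 1], sigma) for i in range(n)]
    )
    return maps


def _regime_sequence(
    T: int, dwell_mean: float, rng: np.random.Generator
) -> np.ndarray:
    """3-state semi-Markov chain with geometric dwell times.

    From Neutral the chain polarizes High or Low with equal probability;
    from a polarized regime it mostly relaxes to Neutral (p = 0.7) but can
    swing to the opposite pole.
    """
    p_leave = min(1.0, 1.0 / dwell_mean)
    labels = np.empty(T, dtype=object)
    state = "Neutral"
    t = 0
    while t < T:
        dwell = rng.geometric(p_leave)
        labels[t : t + dwell] = state
        t += dwell
        if state == "Neutral":
            state = "High" if rng.random() < 0.5 else "Low"
        else:
            if rng.random() < 0.7:
                state = "Neutral"
            else:
                state = "Low" if state == "High" else "High"
    return labels.astype("U7")


def _network_timecourses(
    config: SimulationConfig, g: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited network timecourses with block correlation structure.

    The first half of the networks shares a latent drive (so dFNC has
    nontrivial states to find) and every network is weakly coupled to the
    polarity regime indicator g(t).
    """
    n, T = config.n_networks, config.n_timepoints
    noise = rng.standard_normal((n, T))
    latent = rng.standard_normal(T)
    block = np.zeros((n, T))
    block[: max(1, n // 2)] = latent
    raw = noise + 0.8 * block + 0.4 * g[None, :]
    tcs = bandpass_timecourses(raw, tr_seconds=config.tr_seconds)
    sd = tcs.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return tcs / sd


def generate_subject(
    config: SimulationConfig, group: str, subject_seed: int
) -> SyntheticSubject:
    """Simulate one subject's masked 4D volume plus its ground truth."""
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(subject_seed)]))
    coords = _mask_coords(config.grid_shape)
    V, T = coords.shape[0], config.n_timepoints
    s_v = participation_field(config)
    net_maps = generate_network_maps(config)

    regimes = _regime_sequence(T, config.regime_dwell_mean, rng)
    g = np.zeros(T)
    g[regimes == "High"] = 1.0
    g[regimes == "Low"] = -1.0

    base_gain = (
        config.polarization_gain_hc if group == "HC" else config.polarization_gain_sz
    )
    suppression = 0.0
    if group == "SZ":
        suppression = rng.uniform(0.0, 1.0)
        gain = base_gain * (1.0 - 0.4 * suppression)
    else:
        gain = base_gain * rng.uniform(0.9, 1.1)

    tcs = _network_timecourses(config, g, rng)
    data = (
        gain * s_v[:, None] * g[None, :]
        + config.network_amplitude * (net_maps.T @ tcs)
        + rng.normal(0.0, config.noise_sd, size=(V, T))
    )

    mean_fd = float(rng.lognormal(-1.6, 0.4))
    if config.confounded_motion and group == "SZ":
        mean_fd *= 1.5
    meta = {
        "group": group,
        "age": float(rng.uniform(18.0, 65.0)),
        "gender": "M" if rng.random() < 0.5 else "F",
        "mean_fd": mean_fd,
        "sympt_pos": np.nan,
        "sympt_neg": np.nan,
        "sympt_gen": np.nan,
    }
    if group == "SZ":
        # PANSS-like scales; positive symptoms track the gain suppression
        meta["sympt_pos"] = float(
            np.clip(7.0 + 24.0 * suppression + rng.normal(0.0, 2.0), 7.0, 49.0)
        )
        meta["sympt_neg"] = float(np.clip(rng.normal(18.0, 5.0), 7.0, 49.0))
        meta["sympt_gen"] = float(np.clip(rng.normal(36.0, 8.0), 16.0, 112.0))

    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    volume = MaskedVolumeSeries(
        data=data,
        coords=coords,
        grid_shape=tuple(config.grid_shape),
        affine=affine,
        tr_seconds=config.tr_seconds,
    )
    return SyntheticSubject(
        subject_id="",
        group=group,
        volume=volume,
        true_regime_sequence=regimes,
        true_participation_map=s_v,
        network_timecourses=tcs,
        metadata_row=meta,
    )


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Simulate the full cohort and its metadata table.

    Per-subject seeds derive deterministically from ``config.seed``; HC
    rows precede SZ rows; symptom columns are blank (NaN) for controls.
    """
    if config.n_hc + config.n_sz < 2:
        raise ValueError("need at least 2 subjects in the cohort")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    n = config.n_hc + config.n_sz
    subject_seeds = rng.integers(0, 2**31 - 1, size=n)
    groups = ["HC"] * config.n_hc + ["SZ"] * config.n_sz
    subjects, rows = [], []
    for i, (grp, sd) in enumerate(zip(groups, subject_seeds)):
        subj = generate_subject(config, grp, int(sd))
        subj.subject_id = f"sub-{i:03d}"
        subj.metadata_row = {"subject_id": subj.subject_id, **subj.metadata_row}
        subjects.append(subj)
        rows.append(subj.metadata_row)
    table = pd.DataFrame(rows)
    return subjects, table


def generate_transition_fixture(
    n_states: int,
    scenario: str,
    seed: int = 0,
    cycle_length: int | None = None,
) -> np.ndarray:
    """Row-stochastic matrix with a known most-probable-itinerary structure.

    "cycle" embeds a dominant circuit over the first ``cycle_length``
    states (default min(9, n_states)); "oscillation" embeds a dominant
    2-state alternation; "random" draws Dirichlet rows.  In the structured
    scenarios every state outside the embedded attractor feeds into it, so
    the most-probable distinct-state walk from any source recovers the
    planted orbit.
    """
    if n_states < 2:
        raise ValueError("need at least 2 states")
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.01, 0.05, size=(n_states, n_states))
    if scenario == "random":
        mat = rng.dirichlet(np.ones(n_states), size=n_states)
        return mat
    if scenario == "cycle":
        L = min(9, n_states) if cycle_length is None else cycle_length
        if not 2 <= L <= n_states:
            raise ValueError(f"cycle_length must be in [2, {n_states}]")
        for i in range(L):
            base[i, (i + 1) % L] = 1.0
        for i in range(L, n_states):
            base[i, i % L] = 1.0
    elif scenario == "oscillation":
        base[0, 1] = 1.0
        base[1, 0] = 1.0
        for i in range(2, n_states):
            base[i, 0] = 1.0
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return base / base.sum(axis=1, keepdims=True)


def write_cohort(
    subjects: list[SyntheticSubject],
    table: pd.DataFrame,
    out_dir: str | Path,
    config: SimulationConfig | None = None,
) -> None:
    """Write a simulated cohort to disk: NIfTI volumes, mask, maps, CSVs."""
    from . import io as bio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "cohort.csv", index=False)
    first = subjects[0].volume
    bio.write_masked_series(first, out / f"{subjects[0].subject_id}_bold.nii.gz",
                            out / "mask.nii.gz")
    for subj in subjects[1:]:
        bio.write_masked_series(subj.volume, out / f"{subj.subject_id}_bold.nii.gz")
    for subj in subjects:
        pd.DataFrame(subj.network_timecourses.T).to_csv(
            out / f"{subj.subject_id}_network_tcs.csv", index=False
        )
    if config is not None:
        net = generate_network_maps(config)
        import nibabel as nib

        stack = np.stack([first.unmask(m) for m in net], axis=-1)
        nib.save(nib.Nifti1Image(stack.astype(np.float32), first.affine),
                 out / "network_maps.nii.gz")
        (out / "config.txt").write_text(
            "\n".join(
                f"{k} = {','.join(map(str, v)) if isinstance(v, tuple) else v}"
                for k, v in asdict(config).items()
            )
            + "\n"
        )
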