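"""Disk I/O for masked 4D volumes, cohort tables and fitted state models.

Volumes travel as NIfTI-1; the in-memory container is :class:`MaskedVolumeSeries`,
a dense ``V x T`` matrix over the nonzero voxels of a binary gray-matter mask.
Voxel order is a fixed lexicographic linearization of the mask coordinates
(ascending first axis, then second, then third), so two loads of the same
files always produce identical matrices.

Data are stored float64 in memory and float32 on disk; the downstream
analysis is rank/tercile based and insensitive to the truncation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .regimes import StateModel

logger = logging.getLogger("brainpolarity")

_MODEL_SCHEMA_VERSION = 1


@dataclass
class MaskedVolumeSeries:
    """A 4D volume restricted to the voxels of a binary mask.

    Attributes
    ----------
    data : ndarray, shape (V, T)
        One row per mask voxel, in lexicographic coordinate order.
    coords : ndarray, shape (V, 3)
        Integer voxel coordinates of each row within ``grid_shape``.
    grid_shape : tuple of int
        Shape of the originating 3D grid.
    affine : ndarray, shape (4, 4)
        Voxel-to-world affine.
    tr_seconds : float
        Sampling interval (TR) of the time axis.
    """

    data: np.ndarray
    coords: np.ndarray
    grid_shape: tuple[int, int, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    tr_seconds: float = 2.0

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def mask_volume(self) -> np.ndarray:
        """Rebuild the binary 3D mask from the stored coordinates."""
        mask = np.zeros(self.grid_shape, dtype=np.uint8)
        mask[tuple(self.coords.T)] = 1
        return mask

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a V-vector (or V x K matrix) back onto the 3D grid."""
        values = np.asarray(values)
        shape = self.grid_shape + values.shape[1:]
        out = np.full(shape, fill, dtype=float)
        out[tuple(self.coords.T)] = values
        return out


def _lexicographic_order(coords: np.ndarray) -> np.ndarray:
    # np.lexsort keys are least-significant first
    return np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))


def load_masked_series(
    volume_path: str | Path,
    mask_path: str | Path,
    tr_seconds: float | None = None,
    drop_constant: bool = True,
) -> MaskedVolumeSeries:
    """Load a 4D NIfTI volume restricted to a 3D binary mask.

    Parameters
    ----------
    volume_path, mask_path
        Paths to the 4D data and the 3D binary mask.
    tr_seconds
        Override for the TR; read from the NIfTI header when omitted.
    drop_constant
        Exclude zero-variance voxel rows (z-scoring is undefined for them);
        each exclusion is logged.
    """
    vol_img = nib.load(str(volume_path))
    mask_img = nib.load(str(mask_path))
    vol = np.asarray(vol_img.dataobj)
    mask = np.asarray(mask_img.dataobj)
    if vol.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {vol.shape}")
    if mask.ndim != 3:
        raise ValueError(f"expected a 3D mask, got shape {mask.shape}")
    if vol.shape[:3] != mask.shape:
        raise ValueError(
            f"volume grid {vol.shape[:3]} does not match mask grid {mask.shape}"
        )
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"mask is not binary; values found: {uniq}")
    if vol.shape[3] < 3:
        raise ValueError(f"need at least 3 timepoints, got {vol.shape[3]}")
    coords = np.argwhere(mask > 0)
    if coords.shape[0] == 0:
        raise ValueError("empty mask: no nonzero voxels")
    coords = coords[_lexicographic_order(coords)]
    data = vol[tuple(coords.T)].astype(np.float64)

    if drop_constant:
        sd = data.std(axis=1)
        constant = sd == 0
        if constant.any():
            logger.warning(
                "excluding %d constant voxel(s) from the mask", int(constant.sum())
            )
            data = data[~constant]
            coords = coords[~constant]
        if data.shape[0] == 0:
            raise ValueError("all mask voxels are constant in time")

    if tr_seconds is None:
        zooms = vol_img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return MaskedVolumeSeries(
        data=data,
        coords=coords,
        grid_shape=tuple(mask.shape),
        affine=np.asarray(vol_img.affine, dtype=float),
        tr_seconds=float(tr_seconds),
    )


def write_masked_series(
    series: MaskedVolumeSeries,
    volume_path: str | Path,
    mask_path: str | Path | None = None,
) -> None:
    """Write a masked series back out as a float32 4D NIfTI (+ optional mask)."""
    vol = np.zeros(series.grid_shape + (series.n_timepoints,), dtype=np.float32)
    vol[tuple(series.coords.T)] = series.data.astype(np.float32)
    img = nib.Nifti1Image(vol, series.affine)
    img.header.set_zooms(img.header.get_zooms()[:3] + (series.tr_seconds,))
    nib.save(img, str(volume_path))
    if mask_path is not None:
        nib.save(
            nib.Nifti1Image(series.mask_volume().astype(np.uint8), series.affine),
            str(mask_path),
        )


def write_map(
    values: np.ndarray, series: MaskedVolumeSeries, path: str | Path
) -> None:
    """Write a per-voxel statistic map as a 3D NIfTI aligned with ``series``."""
    nib.save(
        nib.Nifti1Image(series.unmask(values).astype(np.float32), series.affine),
        str(path),
    )


# ---------------------------------------------------------------------------
# state-model serialization


def write_state_model(model: StateModel, path: str | Path) -> None:
    payload = {
        "schema_version": _MODEL_SCHEMA_VERSION,
        "k": int(model.k),
        "seed": int(model.seed),
        "centroids": np.asarray(model.centroids).tolist(),
        "labels": [np.asarray(l).astype(int).tolist() for l in model.labels],
        "occupancy": np.asarray(model.occupancy).tolist(),
        "state_names": list(model.state_names) if model.state_names else None,
        "inertia_curve": (
            [[int(k), float(v)] for k, v in model.inertia_curve]
            if model.inertia_curve
            else None
        ),
    }
    Path(path).write_text(json.dumps(payload))


def read_state_model(path: str | Path) -> StateModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"cannot parse state model file {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != _MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"state model schema version {version!r} not supported "
            f"(expected {_MODEL_SCHEMA_VERSION})"
        )
    return StateModel(
        centroids=np.asarray(payload["centroids"], dtype=float),
        labels=[np.asarray(l, dtype=int) for l in payload["labels"]],
        occupancy=np.asarray(payload["occupancy"], dtype=float),
        k=int(payload["k"]),
        seed=int(payload["seed"]),
        state_names=payload.get("state_names"),
        inertia_curve=(
            [(int(k), float(v)) for k, v in payload["inertia_curve"]]
            if payload.get("inertia_curve")
            else None
        ),
    )
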