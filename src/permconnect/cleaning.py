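"""BOLD quality control and the cleaning chain.

The cleaning order is fixed: nuisance OLS regression (motion-component time
courses, CSF, lesion-flagged component time courses and a discrete high-pass
cosine basis) -> per-voxel z-scoring -> Gaussian smoothing -> probabilistic
parcellation to node time series.  Quality control excludes runs whose mean
framewise displacement exceeds 0.5 mm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "QCRecord",
    "NuisanceDesign",
    "NodeTimeSeriesMatrix",
    "compute_framewise_displacement",
    "apply_fd_exclusion",
    "build_cosine_basis",
    "regress_nuisance",
    "zscore_series",
    "gaussian_smooth",
    "parcellate",
    "clean_subject",
]

FD_ROTATION_RADIUS_MM = 50.0
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class QCRecord:
    subject_id: str
    mean_fd_mm: float
    max_fd_mm: float
    excluded: bool = False
    reason: str = ""


@dataclass
class NodeTimeSeriesMatrix:
    """T x N matrix of cleaned node signals for one subject."""

    values: np.ndarray
    node_labels: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be T x N")
        if self.values.shape[1] != len(self.node_labels):
            raise ValueError("node_labels length does not match columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("node time series contain non-finite values")


class NuisanceDesign:
    """Named nuisance regressors plus an explicit intercept.

    Columns are stored in insertion order; ``matrix`` appends the intercept
    last and prunes exactly collinear columns by QR in input order, with a
    logged warning, so the OLS fit is always full rank.
    """

    def __init__(self, n_timepoints: int):
        self.n_timepoints = int(n_timepoints)
        self.columns: dict[str, np.ndarray] = {}

    def add(self, name: str, series: np.ndarray) -> "NuisanceDesign":
        series = np.asarray(series, dtype=float).ravel()
        if series.shape[0] != self.n_timepoints:
            raise ValueError(
                f"column {name!r} has length {series.shape[0]}, expected {self.n_timepoints}"
            )
        if name in self.columns:
            raise ValueError(f"duplicate design column {name!r}")
        self.columns[name] = series
        return self

    def add_frame(self, frame: pd.DataFrame, prefix: str = "") -> "NuisanceDesign":
        for name in frame.columns:
            self.add(f"{prefix}{name}", frame[name].to_numpy())
        return self

    def matrix(self, include_intercept: bool = True) -> tuple[np.ndarray, list[str]]:
        names = list(self.columns)
        cols = [self.columns[n] for n in names]
        if include_intercept:
            names.append("intercept")
            cols.append(np.ones(self.n_timepoints))
        X = np.column_stack(cols) if cols else np.empty((self.n_timepoints, 0))
        keep = _independent_columns(X)
        if len(keep) < X.shape[1]:
            dropped = [names[i] for i in range(X.shape[1]) if i not in keep]
            log.warning("design matrix rank-deficient; dropping columns %s", dropped)
            X = X[:, keep]
            names = [names[i] for i in keep]
        return X, names


def _independent_columns(X: np.ndarray, tol: float = 1e-10) -> list[int]:
    """Indices of a maximal independent column subset, greedily in input order."""
    keep: list[int] = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, j]
        if basis.shape[1]:
            proj = basis @ np.linalg.lstsq(basis, col, rcond=None)[0]
            resid = col - proj
        else:
            resid = col
        if np.linalg.norm(resid) > tol * max(1.0, np.linalg.norm(col)):
            keep.append(j)
            basis = np.column_stack([basis, col])
    return keep


def compute_framewise_displacement(motion_params: np.ndarray,
                                   radius_mm: float = FD_ROTATION_RADIUS_MM) -> np.ndarray:
    """Power framewise displacement from T x 6 motion parameters.

    Columns 0-2 are translations in mm, 3-5 rotations in radians; rotations
    are converted to arc length at ``radius_mm``.  FD of the first frame is 0.
    """
    motion = np.asarray(motion_params, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion parameters must be a T x 6 array")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    d = np.diff(motion, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def apply_fd_exclusion(records: list[QCRecord], threshold_mm: float = 0.5) -> list[QCRecord]:
    """Flag subjects whose mean FD strictly exceeds the threshold.

    The rule is a strict inequality: a run at exactly the threshold is kept.
    Returns the retained records; exclusion decisions are logged and written
    back onto the input records.
    """
    retained = []
    for rec in records:
        if rec.mean_fd_mm > threshold_mm:
            rec.excluded = True
            rec.reason = f"mean FD {rec.mean_fd_mm:.3f} mm > {threshold_mm} mm"
            log.info("excluding %s: %s", rec.subject_id, rec.reason)
        else:
            rec.excluded = False
            rec.reason = ""
            retained.append(rec)
    return retained


def build_cosine_basis(n_timepoints: int, tr_seconds: float,
                       cutoff_period_s: float = 128.0) -> np.ndarray:
    """DCT-II high-pass regressors with frequencies strictly below 1/cutoff.

    Component k (k >= 1) of the discrete cosine basis has frequency
    k / (2 T TR); all components below the cutoff frequency are returned,
    unit-normalized, constant term excluded (the intercept is a separate
    design column).  A cutoff shorter than 2 TR admits no component.
    """
    T = int(n_timepoints)
    if T < 2:
        raise ValueError("need at least 2 timepoints")
    if tr_seconds <= 0:
        raise ValueError("TR must be > 0")
    if not np.isfinite(cutoff_period_s):
        return np.empty((T, 0))
    if cutoff_period_s < 2 * tr_seconds:
        warnings.warn(
            f"cutoff {cutoff_period_s} s is below the 2*TR Nyquist period; "
            "no high-pass regressors built",
            stacklevel=2,
        )
        return np.empty((T, 0))
    n_k = min(T - 1, int(np.ceil(2 * T * tr_seconds / cutoff_period_s)) - 1)
    # strict inequality k/(2 T TR) < 1/cutoff
    while n_k >= 1 and n_k / (2 * T * tr_seconds) >= 1.0 / cutoff_period_s:
        n_k -= 1
    if n_k < 1:
        warnings.warn(
            f"cutoff {cutoff_period_s} s admits no cosine component at T={T}, TR={tr_seconds}",
            stacklevel=2,
        )
        return np.empty((T, 0))
    t = np.arange(T)
    basis = np.column_stack(
        [np.cos(np.pi * k * (2 * t + 1) / (2 * T)) for k in range(1, n_k + 1)]
    )
    return basis / np.linalg.norm(basis, axis=0)


def regress_nuisance(series: np.ndarray, design: NuisanceDesign | np.ndarray) -> np.ndarray:
    """OLS residuals of one or many series against the nuisance design.

    ``series`` may be a length-T vector or a T x M matrix (voxels/nodes in
    columns).  Residuals are orthogonal to every retained design column.
    """
    if isinstance(design, NuisanceDesign):
        X, _ = design.matrix()
    else:
        X = np.asarray(design, dtype=float)
        keep = _independent_columns(X)
        if len(keep) < X.shape[1]:
            log.warning("design matrix rank-deficient; dropping %d columns",
                        X.shape[1] - len(keep))
            X = X[:, keep]
    Y = np.asarray(series, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    if Y.shape[0] != X.shape[0]:
        raise ValueError(f"series length {Y.shape[0]} != design rows {X.shape[0]}")
    if X.shape[1] == 0:
        resid = Y.copy()
    else:
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
    return resid[:, 0] if squeeze else resid


def zscore_series(series: np.ndarray, axis: int = 0) -> np.ndarray:
    """Standardize to mean 0, population (divide-by-T) SD 1 along ``axis``.

    Zero-variance series are mapped to all-zeros with a warning rather than
    NaN, so constant voxels outside the head stay inert downstream.
    """
    x = np.asarray(series, dtype=float)
    mean = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)  # population convention (ddof=0)
    zero = sd == 0
    if np.any(zero):
        warnings.warn("zero-variance series z-scored to all zeros", stacklevel=2)
    sd = np.where(zero, 1.0, sd)
    return np.where(np.broadcast_to(zero, x.shape), 0.0, (x - mean) / sd)


def gaussian_smooth(volume4d: np.ndarray, fwhm_mm: float = 6.0,
                    voxel_size_mm: float = 3.0,
                    brain_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-frame separable Gaussian smoothing at the given FWHM.

    sigma_voxels = (fwhm / voxel_size) / (2 sqrt(2 ln 2)); fwhm = 0 is the
    identity.  Outside-mask values are zero-padded and the result renormalized
    by the smoothed mask, so signal does not bleed across the brain boundary.
    """
    vol = np.asarray(volume4d, dtype=float)
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return vol.copy()
    sigma_vox = (fwhm_mm / voxel_size_mm) * FWHM_TO_SIGMA
    sigma = (sigma_vox, sigma_vox, sigma_vox, 0.0) if vol.ndim == 4 else sigma_vox
    if brain_mask is None:
        return ndimage.gaussian_filter(vol, sigma=sigma, mode="constant")
    mask = (np.asarray(brain_mask) > 0).astype(float)
    masked = vol * (mask[..., None] if vol.ndim == 4 else mask)
    sm = ndimage.gaussian_filter(masked, sigma=sigma, mode="constant")
    norm = ndimage.gaussian_filter(mask, sigma=sigma_vox, mode="constant")
    norm = np.where(norm > 1e-12, norm, 1.0)
    out = sm / (norm[..., None] if vol.ndim == 4 else norm)
    return out * (mask[..., None] if vol.ndim == 4 else mask)


def parcellate(volume4d: np.ndarray, atlas_maps: np.ndarray,
               brain_mask: np.ndarray | None = None,
               node_labels: list[str] | None = None,
               subject_id: str = "") -> NodeTimeSeriesMatrix:
    """Probabilistic-atlas signal extraction: map-weighted voxel means.

    Each node series is the weighted mean of voxel series, weights given by
    the node's probabilistic map (restricted to the brain mask) and normalized
    to sum to one.  Node order follows the atlas map order.
    """
    vol = np.asarray(volume4d, dtype=float)
    maps = np.asarray(atlas_maps, dtype=float)
    if vol.shape[:3] != maps.shape[:3]:
        raise ValueError("volume and atlas grids are not congruent")
    n_nodes = maps.shape[-1]
    if node_labels is None:
        node_labels = [f"node{i}" for i in range(n_nodes)]
    flat_vol = vol.reshape(-1, vol.shape[-1])
    flat_maps = maps.reshape(-1, n_nodes).copy()
    if brain_mask is not None:
        if brain_mask.shape != vol.shape[:3]:
            raise ValueError("brain mask grid is not congruent with the volume")
        flat_maps[np.asarray(brain_mask).reshape(-1) <= 0] = 0.0
    weight_sums = flat_maps.sum(axis=0)
    dead = np.flatnonzero(weight_sums == 0)
    if dead.size:
        raise ValueError(
            "atlas maps with no in-mask weight for nodes: "
            + ", ".join(node_labels[i] for i in dead)
        )
    series = (flat_maps / weight_sums).T @ flat_vol  # N x T
    return NodeTimeSeriesMatrix(values=series.T, node_labels=list(node_labels),
                                subject_id=subject_id)


def clean_subject(
    bold: np.ndarray,
    design: NuisanceDesign,
    atlas_maps: np.ndarray,
    brain_mask: np.ndarray | None = None,
    fwhm_mm: float = 6.0,
    voxel_size_mm: float = 3.0,
    node_labels: list[str] | None = None,
    subject_id: str = "",
) -> NodeTimeSeriesMatrix:
    """Full cleaning chain for one subject's 4D volume.

    Order (fixed, logged): nuisance OLS regression -> per-voxel z-scoring ->
    Gaussian smoothing -> probabilistic parcellation.
    """
    log.info("cleaning %s: regress -> zscore -> smooth(%g mm) -> parcellate",
             subject_id or "<subject>", fwhm_mm)
    vol = np.asarray(bold, dtype=float)
    T = vol.shape[-1]
    flat = vol.reshape(-1, T).T  # T x voxels
    resid = regress_nuisance(flat, design)
    with warnings.catch_warnings():
        # constant out-of-brain voxels are expected; their z-score is 0
        warnings.simplefilter("ignore")
        z = zscore_series(resid, axis=0)
    zvol = z.T.reshape(vol.shape)
    smoothed = gaussian_smooth(zvol, fwhm_mm=fwhm_mm, voxel_size_mm=voxel_size_mm,
                               brain_mask=brain_mask)
    return parcellate(smoothed, atlas_maps, brain_mask=brain_mask,
                      node_labels=node_labels, subject_id=subject_id)
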