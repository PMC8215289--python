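"""Lesion-artifact component flagging.

Stroke lesions distort the BOLD signal locally, and ICA components that load
on the lesion site carry mostly aberrant signal.  A component is flagged as
lesion-related when the Jaccard overlap between its thresholded spatial map
and the subject's binary lesion mask is at least 5%; flagged components that
were not already labelled motion-related are added to the subject's nuisance
design so their time courses are regressed out.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "ComponentMap",
    "threshold_component_map",
    "jaccard_index",
    "flag_lesion_components",
]

JACCARD_FLAG_THRESHOLD = 0.05


@dataclass
class ComponentMap:
    """One ICA-like component: spatial z-map + time course + motion label."""

    component_id: str
    spatial_z: np.ndarray
    time_course: np.ndarray
    motion_flagged: bool = False


def threshold_component_map(spatial_z: np.ndarray, alpha: float = 0.05,
                            two_sided: bool = True) -> np.ndarray:
    """Binarize a component z-map at the Normal quantile for significance alpha.

    Two-sided by default (|z| >= 1.95996 at alpha = 0.05), since ICA spatial
    maps are signed; a one-sided mode (z >= 1.645) is available.
    """
    z = np.asarray(spatial_z, dtype=float)
    if two_sided:
        crit = stats.norm.ppf(1 - alpha / 2)
        return (np.abs(z) >= crit).astype(np.uint8)
    crit = stats.norm.ppf(1 - alpha)
    return (z >= crit).astype(np.uint8)


def jaccard_index(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """|A intersect B| / |A union B| for two binary masks on the same grid.

    Defined as 0 when both masks are empty (logged).
    """
    a = np.asarray(mask_a) > 0
    b = np.asarray(mask_b) > 0
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        log.info("jaccard_index: both masks empty; returning 0")
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def flag_lesion_components(
    components: list[ComponentMap],
    lesion_mask: np.ndarray | None,
    threshold: float = JACCARD_FLAG_THRESHOLD,
    alpha: float = 0.05,
    two_sided: bool = True,
) -> pd.DataFrame:
    """Apply the lesion-overlap rule to every component.

    A component is ``lesion_flagged`` when its thresholded map's Jaccard
    overlap with the lesion mask is >= ``threshold`` (boundary inclusive), and
    ``added_to_design`` when it is lesion-flagged but not already
    motion-flagged (motion components are in the design regardless and are
    not re-added).  An empty or missing lesion mask (TIA subjects and
    controls have none) yields an all-unflagged table with a warning.
    """
    rows = []
    empty = lesion_mask is None or not np.any(np.asarray(lesion_mask) > 0)
    if empty and components:
        warnings.warn("empty lesion mask: no components flagged", stacklevel=2)
    for comp in components:
        if empty:
            jac = 0.0
        else:
            binary = threshold_component_map(comp.spatial_z, alpha=alpha, two_sided=two_sided)
            jac = jaccard_index(binary, lesion_mask)
        flagged = (not empty) and jac >= threshold
        rows.append(
            {
                "component_id": comp.component_id,
                "jaccard": jac,
                "motion_flagged": bool(comp.motion_flagged),
                "lesion_flagged": flagged,
                "added_to_design": flagged and not comp.motion_flagged,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["component_id", "jaccard", "motion_flagged", "lesion_flagged",
                 "added_to_design"],
    )
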