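"""Synthetic rs-fMRI cohort generator with known ground truth.

Emulates the data structure of a three-group minor-cerebrovascular-event
study — healthy controls, TIA patients (no infarct) and minor-stroke patients
(MRI-confirmed infarct) — so that every downstream stage (cleaning, lesion
flagging, connectivity, permutation inference, cohort statistics) can be
exercised against a generative model whose parameters are known exactly.

What is simulated per subject:

* an 11-node Gaussian graphical signal: rows of the node-signal matrix are
  i.i.d. draws from N(0, inv(Omega_g)) where Omega_g is the group's precision
  matrix, so the true partial correlations are -Omega_ij/sqrt(Omega_ii Omega_jj);
* a 4D BOLD volume built by mixing the node signals through probabilistic
  Gaussian-blob atlas maps, plus motion / CSF / drift nuisance mixtures and
  white noise (160 volumes at TR = 3.12 s by default);
* an ICA-like component set (spatial z-maps, time courses, motion flags), with
  a lesion-artifact component of known spatial overlap injected for stroke
  subjects;
* a phenotype record: age (truncated normal), vascular-risk-factor count
  (group-dependent Poisson), and cognitive scores generated as
  b0 + b1*edge + b2*group + b3*edge*group + slopes.(age, vrf) + noise, where
  "edge" is the subject's realized partial correlation on a designated node
  pair — the interaction structure the brain-behaviour regression must recover.

The generator is fully deterministic under (spec, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import (
    DEFAULT_NODE_LABELS,
    DEFAULT_NODE_NETWORKS,
    partial_correlation,
    partial_correlation_from_precision,
)

__all__ = [
    "GROUPS",
    "CognitionModel",
    "GroundTruthEffects",
    "CohortSpec",
    "ComponentSet",
    "SubjectRecord",
    "Cohort",
    "default_effects",
    "recovery_benchmark_precision",
    "make_atlas",
    "simulate_node_signals",
    "simulate_motion_params",
    "embed_signals_in_volume",
    "simulate_cognition",
    "simulate_cohort",
    "write_cohort",
]

GROUPS = ("control", "tia", "stroke")

# mm displacement per radian at the conventional 50 mm head radius
HEAD_RADIUS_MM = 50.0


# ---------------------------------------------------------------------------
# ground-truth parameterization
# ---------------------------------------------------------------------------


@dataclass
class CognitionModel:
    """Generative model for one cognitive score.

    score = b0 + b1*edge + b2*group + b3*edge*group
            + age_slope*(age - 70) + vrf_slope*vrf + N(0, noise_sd)

    ``group_coding`` maps each group name to its 0/1 indicator so the same
    machinery expresses both a control-vs-CVE and a stroke-vs-TIA contrast.
    """

    edge_key: tuple[str, str]
    b0: float = 0.0
    b_edge: float = 0.0
    b_group: float = 0.0
    b_interaction: float = 0.0
    age_slope: float = 0.0
    vrf_slope: float = 0.0
    noise_sd: float = 1.0
    group_coding: Mapping[str, int] = field(
        default_factory=lambda: {"control": 0, "tia": 1, "stroke": 1}
    )

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be > 0")


@dataclass
class GroundTruthEffects:
    """All data-generating parameters for one synthetic cohort."""

    group_precision_matrices: Mapping[str, np.ndarray]
    cognition_models: Mapping[str, CognitionModel]
    vrf_age_slope: float = 0.02  # E[VRF] increase per year of age, confounding channel
    lesion_artifact_amplitude: float = 2.0
    lesion_artifact_overlap: float = 0.30
    motion_amplitude: float = 0.5
    csf_amplitude: float = 0.5
    drift_amplitude: float = 0.5
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        for g, omega in self.group_precision_matrices.items():
            omega = np.asarray(omega, dtype=float)
            if not np.allclose(omega, omega.T):
                raise ValueError(f"precision matrix for group {g!r} is not symmetric")
            try:
                np.linalg.cholesky(omega)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"precision matrix for group {g!r} is not positive-definite"
                ) from exc


def _precision_from_partials(partials: Mapping[tuple[str, str], float],
                             labels: Sequence[str]) -> np.ndarray:
    """Unit-diagonal precision matrix with the requested partial correlations.

    With Omega_ii = 1, the partial correlation on (i, j) is simply -Omega_ij,
    so Omega = I - R_offdiag.  The caller keeps |rho| small enough for
    positive-definiteness (checked downstream).
    """
    n = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    omega = np.eye(n)
    for (a, b), rho in partials.items():
        i, j = index[a], index[b]
        omega[i, j] = omega[j, i] = -rho
    return omega


def recovery_benchmark_precision(n_nodes: int = len(DEFAULT_NODE_LABELS),
                                 rho: float = 0.7) -> np.ndarray:
    """Dense benchmark precision for estimator-recovery checks.

    ``Omega = (1 - rho) I + rho s s^T`` with alternating signs ``s`` puts a
    partial correlation of magnitude ``rho`` on every node pair.  With signal
    on all edges the sampling noise of each estimate is ~(1 - rho^2)/sqrt(T),
    so a tight max-error bound on the recovered edge vector probes estimator
    correctness rather than the noise floor of near-zero edges.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    s = np.where(np.arange(n_nodes) % 2 == 0, 1.0, -1.0)
    return (1 - rho) * np.eye(n_nodes) + rho * np.outer(s, s)


def default_effects(node_labels: Sequence[str] = DEFAULT_NODE_LABELS) -> GroundTruthEffects:
    """Default generative parameters.

    The base connectome has modest positive partial correlations within each
    network and weak between-network coupling.  Group effects are planted on a
    handful of edges: stroke differs from TIA on one intra-DMN and one
    intra-FPN edge, and both patient groups differ from controls on one
    FPN<->DMN edge — mirroring the kind of contrasts the inference stage is
    meant to detect.  One executive-speed score and one vocabulary-like score
    carry confound structure (age, vascular-risk-factor count) and an
    edge-by-group interaction.
    """
    dmn = [n for n in node_labels if DEFAULT_NODE_NETWORKS.get(n) == "DMN"]
    fpn = [n for n in node_labels if DEFAULT_NODE_NETWORKS.get(n) == "FPN"]

    base: dict[tuple[str, str], float] = {}
    for net in (dmn, fpn):
        for a, b in itertools.combinations(net, 2):
            base[(a, b)] = 0.12
    for a in dmn:
        for b in fpn:
            base[(a, b)] = 0.03

    control = dict(base)
    tia = dict(base)
    stroke = dict(base)

    # patient groups couple the FPN to the DMN more strongly than controls
    tia[("R_DMN", "L_dorsolateral_prefrontal")] += 0.20
    stroke[("R_DMN", "L_dorsolateral_prefrontal")] += 0.20
    # stroke shows stronger intra-network coupling than TIA
    stroke[("M_DMN", "R_DMN")] += 0.20
    stroke[("R_dorsolateral_prefrontal", "R_frontal_pole")] += 0.20

    matrices = {
        "control": _precision_from_partials(control, node_labels),
        "tia": _precision_from_partials(tia, node_labels),
        "stroke": _precision_from_partials(stroke, node_labels),
    }

    cognition = {
        # Trail-making-like speed score: slower with age and vascular burden,
        # and its association with intra-FPN connectivity differs by group
        # (stroke vs TIA contrast).
        "tmt_b_seconds": CognitionModel(
            edge_key=("R_dorsolateral_prefrontal", "R_frontal_pole"),
            b0=85.0,
            b_edge=-40.0,
            b_group=15.0,
            b_interaction=120.0,
            age_slope=1.5,
            vrf_slope=8.0,
            noise_sd=25.0,
            group_coding={"control": 0, "tia": 0, "stroke": 1},
        ),
        # vocabulary-like score: confounded by age, no interaction planted
        "picture_vocabulary": CognitionModel(
            edge_key=("F_DMN", "L_parietal"),
            b0=114.0,
            b_edge=10.0,
            b_group=-3.0,
            b_interaction=0.0,
            age_slope=-0.2,
            vrf_slope=-1.0,
            noise_sd=8.0,
            group_coding={"control": 0, "tia": 1, "stroke": 1},
        ),
    }
    return GroundTruthEffects(group_precision_matrices=matrices, cognition_models=cognition)


@dataclass
class CohortSpec:
    """Sizes, acquisition geometry and generative parameters of a cohort."""

    n_control: int = 20
    n_tia: int = 25
    n_stroke: int = 17
    n_timepoints: int = 160
    tr_seconds: float = 3.12
    grid_shape: tuple[int, int, int] = (20, 20, 12)
    voxel_size_mm: float = 3.0
    seed: int = 0
    effects: GroundTruthEffects | None = None
    node_labels: tuple[str, ...] = DEFAULT_NODE_LABELS
    generate_volumes: bool = True

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_tia, self.n_stroke) < 0:
            raise ValueError("group counts must be >= 0")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 timepoints")
        if self.tr_seconds <= 0:
            raise ValueError("TR must be > 0")
        if self.effects is None:
            self.effects = default_effects(self.node_labels)


# ---------------------------------------------------------------------------
# component and subject containers
# ---------------------------------------------------------------------------


@dataclass
class ComponentSet:
    """ICA-like decomposition products attached to one subject.

    ``true_lesion_overlap`` records, for every component, the Jaccard overlap
    of its (binary) generative support with the subject's lesion mask — NaN
    for subjects without a mask.  This is the ground truth the lesion-flagging
    stage is validated against.
    """

    spatial_maps: np.ndarray  # X x Y x Z x C z-scored maps
    time_courses: pd.DataFrame  # T x C
    motion_flags: np.ndarray  # bool, length C
    true_lesion_overlap: np.ndarray  # float, length C

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[-1]


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    vrf_count: int
    cognitive_scores: dict[str, float]
    node_signals: np.ndarray  # T x N ground-truth signals (pre-embedding)
    motion_params: np.ndarray  # T x 6: 3 translations (mm), 3 rotations (rad)
    bold: np.ndarray | None = None  # X x Y x Z x T
    lesion_mask: np.ndarray | None = None  # X x Y x Z in {0,1}
    components: ComponentSet | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if (self.lesion_mask is not None) != (self.group == "stroke"):
            raise ValueError("lesion mask present iff group == 'stroke'")


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[SubjectRecord]
    atlas_maps: np.ndarray  # X x Y x Z x N probabilistic maps
    node_labels: tuple[str, ...]

    def phenotypes(self) -> pd.DataFrame:
        """BIDS participants.tsv-style phenotype table."""
        score_names = sorted({k for s in self.subjects for k in s.cognitive_scores})
        rows = []
        for s in self.subjects:
            row: dict[str, object] = {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": round(s.age, 4),
                "vrf_count": s.vrf_count,
            }
            for name in score_names:
                row[name] = round(s.cognitive_scores[name], 6)
            rows.append(row)
        cols = ["subject_id", "group", "age", "vrf_count", *score_names]
        return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# generative primitives
# ---------------------------------------------------------------------------


def simulate_node_signals(
    precision: np.ndarray, n_timepoints: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw T i.i.d. rows from N(0, inv(precision)).

    The rows therefore carry exactly the partial-correlation structure
    -Omega_ij/sqrt(Omega_ii Omega_jj) in expectation.
    """
    omega = np.asarray(precision, dtype=float)
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise ValueError("precision must be a square matrix")
    if not np.allclose(omega, omega.T):
        raise ValueError("precision must be symmetric")
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix is not positive-definite") from exc
    cov = np.linalg.inv(omega)
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_timepoints, omega.shape[0]))
    return z @ L.T


def make_atlas(
    grid_shape: tuple[int, int, int],
    n_nodes: int = len(DEFAULT_NODE_LABELS),
    blob_sigma_vox: float = 1.2,
) -> np.ndarray:
    """Probabilistic atlas of Gaussian blobs at fixed, well-separated centers.

    Centers sit on a deterministic lattice spread through the grid interior, so
    identical grids always yield identical maps; values lie in [0, 1].
    """
    nx, ny, nz = grid_shape
    # lay nodes out on a 4 x 3 x ceil(n/12) lattice inside the volume
    per_x, per_y = 4, 3
    centers = []
    for i in range(n_nodes):
        ix, rem = divmod(i, per_x * per_y)
        iy, iz0 = divmod(rem, per_x)
        cx = (iz0 + 1) * nx / (per_x + 1)
        cy = (iy + 1) * ny / (per_y + 1)
        cz = (ix + 1) * nz / (n_nodes // (per_x * per_y) + 2)
        centers.append((cx, cy, cz))
    xs, ys, zs = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    maps = np.zeros((*grid_shape, n_nodes))
    for k, (cx, cy, cz) in enumerate(centers):
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2
        blob = np.exp(-d2 / (2 * blob_sigma_vox**2))
        blob[blob < 0.05] = 0.0
        maps[..., k] = blob
    return np.clip(maps, 0.0, 1.0)


def simulate_motion_params(
    n_timepoints: int,
    rng: np.random.Generator,
    translation_step_mm: float = 0.02,
    rotation_step_rad: float = 3e-4,
) -> np.ndarray:
    """Random-walk head motion: T x 6 (3 translations mm, 3 rotations rad)."""
    steps = np.concatenate(
        [
            rng.normal(0.0, translation_step_mm, size=(n_timepoints, 3)),
            rng.normal(0.0, rotation_step_rad, size=(n_timepoints, 3)),
        ],
        axis=1,
    )
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def _lesion_blob(grid_shape: tuple[int, int, int], rng: np.random.Generator,
                 target_voxels: int = 20) -> np.ndarray:
    """Compact binary lesion of ~target_voxels voxels at a random interior site."""
    nx, ny, nz = grid_shape
    center = np.array(
        [
            rng.integers(nx // 4, 3 * nx // 4),
            rng.integers(ny // 4, 3 * ny // 4),
            rng.integers(max(1, nz // 4), max(2, 3 * nz // 4)),
        ]
    )
    xs, ys, zs = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    d2 = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 + (zs - center[2]) ** 2
    order = np.argsort(d2, axis=None, kind="stable")
    mask = np.zeros(grid_shape, dtype=np.uint8)
    mask.flat[order[:target_voxels]] = 1
    return mask


def _nuisance_pattern(name: str, grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Structured spatial loading for a nuisance component.

    Motion components load as an intensity gradient along one axis (rigid
    displacement mostly perturbs voxels along the movement direction), the
    CSF component as a compact blob at a fixed ventricle-like site, and
    global components (drift and anything unnamed) load uniformly.  Smooth,
    localized patterns mimic real ICA spatial maps; after per-map z-scoring a
    uniform map is inert and a gradient rarely crosses the |z| >= 1.96
    threshold, so only genuinely lesion-supported components can overlap a
    lesion mask.
    """
    xs, ys, zs = np.meshgrid(*(np.arange(n) for n in grid_shape), indexing="ij")
    if name.startswith("motion"):
        axis = {"x": xs, "y": ys, "z": zs}.get(name[-1], xs)
        return axis.astype(float)
    if name == "csf":
        # corner blob, well away from the interior band where lesions sit
        d2 = xs**2 + ys**2 + zs**2
        return np.exp(-d2 / (2 * 1.2**2))
    return np.ones(grid_shape)


def embed_signals_in_volume(
    node_signals: np.ndarray,
    atlas_maps: np.ndarray,
    nuisance: pd.DataFrame | None = None,
    lesion_mask: np.ndarray | None = None,
    artifact_amplitude: float = 0.0,
    artifact_overlap: float = 0.30,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, ComponentSet]:
    """Mix node signals, nuisance series and optional lesion artifact into a 4D volume.

    Voxel series = sum_n map_n * signal_n + sum_j pattern_j * nuisance_j
    + artifact + white noise.  Each nuisance column receives a fixed spatial
    pattern and is returned as an ICA-like component (motion columns flagged
    motion-related).  When a lesion mask is given and ``artifact_amplitude``
    is nonzero, an artifact component whose binary support is a subset of the
    mask with Jaccard overlap ``artifact_overlap`` is injected and recorded in
    the returned :class:`ComponentSet` with its true overlap fraction.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    signals = np.asarray(node_signals, dtype=float)
    T, n_nodes = signals.shape
    if atlas_maps.shape[-1] != n_nodes:
        raise ValueError("atlas map count does not match node signal columns")
    grid_shape = atlas_maps.shape[:-1]
    if lesion_mask is not None and lesion_mask.shape != grid_shape:
        raise ValueError("lesion mask grid does not match the atlas grid")

    flat_maps = atlas_maps.reshape(-1, n_nodes)
    vol = (flat_maps @ signals.T).astype(np.float32)  # voxels x T

    comp_maps: list[np.ndarray] = []
    comp_tc: dict[str, np.ndarray] = {}
    motion_flags: list[bool] = []
    overlaps: list[float] = []

    if nuisance is not None:
        for name in nuisance.columns:
            series = np.asarray(nuisance[name], dtype=float)
            if series.shape[0] != T:
                raise ValueError(f"nuisance column {name!r} has wrong length")
            pattern = _nuisance_pattern(name, grid_shape).ravel()
            vol += np.outer(pattern, series).astype(np.float32)
            comp_maps.append(pattern.reshape(grid_shape))
            comp_tc[name] = series
            motion_flags.append(name.startswith("motion"))
            if lesion_mask is not None:
                support = np.abs(pattern.reshape(grid_shape)) > 1.96
                inter = np.logical_and(support, lesion_mask > 0).sum()
                union = np.logical_or(support, lesion_mask > 0).sum()
                overlaps.append(inter / union if union else 0.0)
            else:
                overlaps.append(np.nan)

    if lesion_mask is not None and artifact_amplitude != 0.0:
        m = int((lesion_mask > 0).sum())
        if m == 0:
            raise ValueError("lesion mask is empty")
        k = max(1, int(round(artifact_overlap * m)))
        support = np.zeros(grid_shape, dtype=bool)
        idx = np.flatnonzero(lesion_mask > 0)[:k]  # deterministic subset
        support.flat[idx] = True
        tc = rng.normal(0.0, 1.0, size=T)
        spatial = np.where(support, float(artifact_amplitude), 0.0)
        vol += np.outer(spatial.ravel(), tc).astype(np.float32)
        comp_maps.append(spatial)
        comp_tc["lesion_artifact"] = tc
        motion_flags.append(False)
        overlaps.append(k / m)

    if noise_sd > 0:
        vol += rng.normal(0.0, noise_sd, size=vol.shape).astype(np.float32)

    if comp_maps:
        stack = np.stack(comp_maps, axis=-1)
        # z-score each spatial map so downstream |z| thresholding is meaningful
        flat = stack.reshape(-1, stack.shape[-1])
        sd = flat.std(axis=0)
        sd[sd == 0] = 1.0
        zmaps = ((flat - flat.mean(axis=0)) / sd).reshape(stack.shape)
        components = ComponentSet(
            spatial_maps=zmaps,
            time_courses=pd.DataFrame(comp_tc),
            motion_flags=np.array(motion_flags, dtype=bool),
            true_lesion_overlap=np.array(overlaps, dtype=float),
        )
    else:
        components = ComponentSet(
            spatial_maps=np.zeros((*grid_shape, 0)),
            time_courses=pd.DataFrame(index=range(T)),
            motion_flags=np.zeros(0, dtype=bool),
            true_lesion_overlap=np.zeros(0),
        )

    return vol.reshape(*grid_shape, T), components


def simulate_cognition(
    edge_value: float,
    group_indicator: int,
    age: float,
    vrf: int,
    model: CognitionModel,
    rng: np.random.Generator,
) -> float:
    """One score draw from the linear edge-by-group interaction model."""
    mean = (
        model.b0
        + model.b_edge * edge_value
        + model.b_group * group_indicator
        + model.b_interaction * edge_value * group_indicator
        + model.age_slope * (age - 70.0)
        + model.vrf_slope * vrf
    )
    return float(mean + rng.normal(0.0, model.noise_sd))


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

_VRF_BASE_MEANS = {"control": 0.6, "tia": 1.0, "stroke": 1.8}


def _draw_age(rng: np.random.Generator) -> float:
    """Age ~ Normal(70, 9) truncated to [45, 90]."""
    a, b = (45 - 70) / 9, (90 - 70) / 9
    return float(stats.truncnorm.rvs(a, b, loc=70, scale=9, random_state=rng))


def _nuisance_frame(T: int, tr: float, motion: np.ndarray, effects: GroundTruthEffects,
                    rng: np.random.Generator) -> pd.DataFrame:
    t = np.arange(T) * tr
    cols = {}
    for j in range(3):
        cols[f"motion_{'xyz'[j]}"] = effects.motion_amplitude * _unitize(motion[:, j])
    csf = rng.normal(size=T)
    csf = np.convolve(csf, np.ones(5) / 5, mode="same")  # slow-ish physiological noise
    cols["csf"] = effects.csf_amplitude * _unitize(csf)
    cols["drift"] = effects.drift_amplitude * _unitize(np.cos(2 * np.pi * t / (t[-1] + tr)))
    return pd.DataFrame(cols)


def _unitize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full cohort per the spec; deterministic under spec.seed."""
    effects = spec.effects
    assert effects is not None
    labels = spec.node_labels
    for g in GROUPS:
        if g not in effects.group_precision_matrices:
            raise ValueError(f"missing precision matrix for group {g!r}")

    atlas = make_atlas(spec.grid_shape, n_nodes=len(labels)) if spec.generate_volumes else (
        np.zeros((*spec.grid_shape, len(labels)))
    )
    edge_index = {k: i for i, k in enumerate(itertools.combinations(labels, 2))}

    ss = np.random.SeedSequence(spec.seed)
    group_plan = (
        [("control", i) for i in range(spec.n_control)]
        + [("tia", i) for i in range(spec.n_tia)]
        + [("stroke", i) for i in range(spec.n_stroke)]
    )
    child_seeds = ss.spawn(len(group_plan))

    subjects: list[SubjectRecord] = []
    for idx, ((group, _), child) in enumerate(zip(group_plan, child_seeds)):
        rng = np.random.default_rng(child)
        sid = f"sub-{idx + 1:03d}"
        age = _draw_age(rng)
        vrf_mean = max(0.05, _VRF_BASE_MEANS[group] + effects.vrf_age_slope * (age - 70.0))
        vrf = int(rng.poisson(vrf_mean))

        omega = effects.group_precision_matrices[group]
        signals = simulate_node_signals(omega, spec.n_timepoints, rng)
        motion = simulate_motion_params(spec.n_timepoints, rng)

        lesion = _lesion_blob(spec.grid_shape, rng) if group == "stroke" else None

        bold = None
        components = None
        if spec.generate_volumes:
            nuis = _nuisance_frame(spec.n_timepoints, spec.tr_seconds, motion, effects, rng)
            bold, components = embed_signals_in_volume(
                signals,
                atlas,
                nuisance=nuis,
                lesion_mask=lesion,
                artifact_amplitude=effects.lesion_artifact_amplitude if group == "stroke" else 0.0,
                artifact_overlap=effects.lesion_artifact_overlap,
                noise_sd=effects.noise_sd,
                rng=rng,
            )

        # subject's realized partial correlations drive the cognition model
        edges = partial_correlation(signals, node_labels=labels, subject_id=sid)
        scores = {}
        for name, model in effects.cognition_models.items():
            key = model.edge_key if model.edge_key in edge_index else model.edge_key[::-1]
            edge_val = float(edges.values[edge_index[key]])
            g01 = int(model.group_coding[group])
            scores[name] = simulate_cognition(edge_val, g01, age, vrf, model, rng)

        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=group,
                age=age,
                vrf_count=vrf,
                cognitive_scores=scores,
                node_signals=signals,
                motion_params=motion,
                bold=bold,
                lesion_mask=lesion,
                components=components,
            )
        )

    return Cohort(spec=spec, subjects=subjects, atlas_maps=atlas, node_labels=tuple(labels))


# ---------------------------------------------------------------------------
# disk round trip (NIfTI + TSV)
# ---------------------------------------------------------------------------


def _ras_affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write volumes, masks, components and phenotypes under ``outdir``.

    Layout: ``participants.tsv``, ``atlas.nii.gz``, ``labels.tsv`` and one
    ``sub-XXX/`` directory per subject with ``bold.nii.gz``,
    ``motion.tsv``, optional ``lesion.nii.gz`` and component files.
    """
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = _ras_affine(cohort.spec.voxel_size_mm)

    cohort.phenotypes().to_csv(outdir / "participants.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "node": cohort.node_labels,
            "network": [DEFAULT_NODE_NETWORKS.get(n, "unknown") for n in cohort.node_labels],
        }
    ).to_csv(outdir / "labels.tsv", sep="\t", index=False)
    nib.save(nib.Nifti1Image(cohort.atlas_maps.astype(np.float32), aff), outdir / "atlas.nii.gz")

    for s in cohort.subjects:
        sdir = outdir / s.subject_id
        sdir.mkdir(exist_ok=True)
        pd.DataFrame(
            s.motion_params,
            columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
        ).to_csv(sdir / "motion.tsv", sep="\t", index=False)
        if s.bold is not None:
            nib.save(nib.Nifti1Image(s.bold.astype(np.float32), aff), sdir / "bold.nii.gz")
        if s.lesion_mask is not None:
            nib.save(
                nib.Nifti1Image(s.lesion_mask.astype(np.uint8), aff), sdir / "lesion.nii.gz"
            )
        if s.components is not None and s.components.n_components:
            nib.save(
                nib.Nifti1Image(s.components.spatial_maps.astype(np.float32), aff),
                sdir / "components.nii.gz",
            )
            s.components.time_courses.to_csv(sdir / "component_timecourses.tsv", sep="\t",
                                             index=False)
            pd.DataFrame(
                {
                    "component_id": s.components.time_courses.columns,
                    "motion_flagged": s.components.motion_flags.astype(int),
                    "true_lesion_overlap": s.components.true_lesion_overlap,
                }
            ).to_csv(sdir / "component_flags.tsv", sep="\t", index=False)
    return outdir
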