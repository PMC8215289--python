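"""End-to-end pipeline: simulate -> QC -> clean -> lesion-flag -> connectivity
-> permutation inference -> cohort statistics -> report.

A single :class:`RunConfig` pins every analysis constant (FD threshold 0.5 mm,
cosine cutoff 128 s, 6 mm FWHM, 5% Jaccard threshold, 10,000 permutations,
Huber epsilon/alpha/tol) and one master seed governs every random draw, so a
run is exactly reproducible from its config.  Results are returned as an
in-memory bundle and optionally written as TSV tables with a provenance
header file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthdata import Cohort, CohortSpec, simulate_cohort
from .cleaning import (
    NuisanceDesign,
    QCRecord,
    apply_fd_exclusion,
    build_cosine_basis,
    clean_subject,
    compute_framewise_displacement,
)
from .lesion_overlap import ComponentMap, flag_lesion_components
from .connectivity import classify_edges, cohort_edge_table, partial_correlation
from .inference import (
    EdgeTestResult,
    HuberSettings,
    InteractionResult,
    PermutationSettings,
    huber_residualize,
    manly_permutation_pvalues,
    maxt_permutation_test,
)
from .cohort_stats import group_summary_table

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "load_config"]

CONTRASTS = {
    # contrast name -> (group A predicate, group B predicate) over group labels
    "control-vs-cve": (("control",), ("tia", "stroke")),
    "stroke-vs-tia": (("stroke",), ("tia",)),
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str | None = None
    # cohort
    n_control: int = 20
    n_tia: int = 25
    n_stroke: int = 17
    n_timepoints: int = 160
    tr_seconds: float = 3.12
    grid_shape: tuple[int, int, int] = (20, 20, 12)
    voxel_size_mm: float = 3.0
    # cleaning / QC
    fd_threshold_mm: float = 0.5
    cosine_cutoff_s: float = 128.0
    fwhm_mm: float = 6.0
    # lesion flagging
    jaccard_threshold: float = 0.05
    component_alpha: float = 0.05
    # inference
    n_permutations: int = 10_000
    huber: HuberSettings = field(default_factory=HuberSettings)
    contrasts: tuple[str, ...] = ("control-vs-cve", "stroke-vs-tia")
    models: tuple[str, ...] = ("raw", "corrected")
    # (score, edge "<nodeA>__<nodeB>") pairs for interaction tests
    interactions: tuple[tuple[str, str], ...] = ()
    # stage toggles
    run_lesion_flagging: bool = True
    run_inference: bool = True
    run_interactions: bool = True

    def __post_init__(self) -> None:
        for name, v in (("fd_threshold_mm", self.fd_threshold_mm),
                        ("cosine_cutoff_s", self.cosine_cutoff_s),
                        ("jaccard_threshold", self.jaccard_threshold)):
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        for c in self.contrasts:
            if c not in CONTRASTS:
                raise ValueError(f"unknown contrast {c!r}; known: {sorted(CONTRASTS)}")

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_control=self.n_control,
            n_tia=self.n_tia,
            n_stroke=self.n_stroke,
            n_timepoints=self.n_timepoints,
            tr_seconds=self.tr_seconds,
            grid_shape=tuple(self.grid_shape),
            voxel_size_mm=self.voxel_size_mm,
            seed=self.seed,
        )


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    huber = HuberSettings(**raw.pop("huber", {}))
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "grid_shape" in raw:
        raw["grid_shape"] = tuple(raw["grid_shape"])
    if "contrasts" in raw:
        raw["contrasts"] = tuple(raw["contrasts"])
    if "models" in raw:
        raw["models"] = tuple(raw["models"])
    if "interactions" in raw:
        raw["interactions"] = tuple((s, e) for s, e in raw["interactions"])
    return RunConfig(huber=huber, **raw)


@dataclass
class RunResult:
    config: RunConfig
    qc: pd.DataFrame
    lesion_flags: pd.DataFrame
    edges: pd.DataFrame
    edge_networks: pd.DataFrame
    edge_tests: pd.DataFrame
    interactions: pd.DataFrame
    summary: pd.DataFrame
    phenotypes: pd.DataFrame
    provenance: dict


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _contrast_labels(groups: pd.Series, contrast: str) -> tuple[np.ndarray, np.ndarray]:
    ga, gb = CONTRASTS[contrast]
    in_a = groups.isin(ga).to_numpy()
    in_b = groups.isin(gb).to_numpy()
    keep = in_a | in_b
    labels = np.where(in_a[keep], "A", "B")
    return keep, labels


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> RunResult:
    """Execute every stage on a (simulated) cohort.

    Stage order is fixed: simulate -> QC -> clean -> lesion-flag ->
    connectivity -> inference -> cohort statistics -> report.  Any stage
    failure is re-raised annotated with the stage and subject.
    """
    stage = "simulate"
    try:
        if cohort is None:
            cohort = simulate_cohort(config.cohort_spec())
        spec = cohort.spec

        # --- QC -----------------------------------------------------------
        stage = "qc"
        records = []
        for s in cohort.subjects:
            fd = compute_framewise_displacement(s.motion_params)
            records.append(QCRecord(subject_id=s.subject_id,
                                    mean_fd_mm=float(fd.mean()),
                                    max_fd_mm=float(fd.max())))
        retained_ids = {r.subject_id for r in
                        apply_fd_exclusion(records, config.fd_threshold_mm)}
        qc = pd.DataFrame([asdict(r) for r in records])
        subjects = [s for s in cohort.subjects if s.subject_id in retained_ids]

        # --- lesion flagging + cleaning + connectivity --------------------
        cosine = build_cosine_basis(spec.n_timepoints, spec.tr_seconds,
                                    config.cosine_cutoff_s)
        flag_tables = []
        edge_vectors = []
        for s in subjects:
            stage = f"lesion-flag[{s.subject_id}]"
            added_components: list[str] = []
            if (config.run_lesion_flagging and s.components is not None
                    and s.lesion_mask is not None):
                comps = [
                    ComponentMap(
                        component_id=str(cid),
                        spatial_z=s.components.spatial_maps[..., i],
                        time_course=s.components.time_courses[cid].to_numpy(),
                        motion_flagged=bool(s.components.motion_flags[i]),
                    )
                    for i, cid in enumerate(s.components.time_courses.columns)
                ]
                flags = flag_lesion_components(
                    comps, s.lesion_mask, threshold=config.jaccard_threshold,
                    alpha=config.component_alpha,
                )
                flags.insert(0, "subject_id", s.subject_id)
                flag_tables.append(flags)
                added_components = list(flags.loc[flags["added_to_design"],
                                                  "component_id"])

            stage = f"clean[{s.subject_id}]"
            if s.bold is not None and s.components is not None:
                design = NuisanceDesign(spec.n_timepoints)
                tc = s.components.time_courses
                for i, cid in enumerate(tc.columns):
                    if s.components.motion_flags[i] or cid == "csf":
                        design.add(str(cid), tc[cid].to_numpy())
                for cid in added_components:
                    design.add(f"lesion_{cid}", tc[cid].to_numpy())
                for k in range(cosine.shape[1]):
                    design.add(f"cosine{k + 1:02d}", cosine[:, k])
                node_ts = clean_subject(
                    s.bold, design, cohort.atlas_maps,
                    fwhm_mm=config.fwhm_mm, voxel_size_mm=spec.voxel_size_mm,
                    node_labels=list(cohort.node_labels), subject_id=s.subject_id,
                )
                series = node_ts
            else:  # volume generation disabled: fall back to the planted signals
                series = s.node_signals

            stage = f"connectivity[{s.subject_id}]"
            edge_vectors.append(
                partial_correlation(series, node_labels=list(cohort.node_labels),
                                    subject_id=s.subject_id)
            )

        lesion_flags = (pd.concat(flag_tables, ignore_index=True) if flag_tables
                        else pd.DataFrame(columns=["subject_id", "component_id", "jaccard",
                                                   "motion_flagged", "lesion_flagged",
                                                   "added_to_design"]))
        edges = cohort_edge_table(edge_vectors)
        keys = edge_vectors[0].edge_keys if edge_vectors else []
        edge_networks = pd.DataFrame(
            {
                "edge": [f"{a}__{b}" for a, b in keys],
                "network_pair": classify_edges(keys) if keys else [],
            }
        )
        pair_of = dict(zip(edge_networks["edge"], edge_networks["network_pair"]))

        pheno = cohort.phenotypes()
        pheno = pheno[pheno["subject_id"].isin(retained_ids)].reset_index(drop=True)

        # --- inference ----------------------------------------------------
        master = np.random.SeedSequence(config.seed).spawn(1)[0]
        seed_stream = iter(np.random.default_rng(master).integers(2**31 - 1, size=4096))
        covs = pheno[["age", "vrf_count"]]
        test_rows = []
        if config.run_inference and len(edges):
            for contrast in config.contrasts:
                stage = f"group-diff[{contrast}]"
                keep, labels = _contrast_labels(pheno["group"], contrast)
                sub_edges = edges.iloc[np.flatnonzero(keep)]
                for model in config.models:
                    if model == "corrected":
                        mat = np.column_stack([
                            huber_residualize(sub_edges[c].to_numpy(),
                                              covs[keep], config.huber)[0]
                            for c in sub_edges.columns
                        ])
                        data = pd.DataFrame(mat, columns=sub_edges.columns)
                    else:
                        data = sub_edges
                    results = maxt_permutation_test(
                        data, labels,
                        PermutationSettings(n_permutations=config.n_permutations,
                                            seed=int(next(seed_stream))),
                        group_a="A", model=model,
                    )
                    for r in results:
                        test_rows.append(
                            {
                                "contrast": contrast,
                                "model": model,
                                "edge": r.edge_key,
                                "network_pair": pair_of.get(r.edge_key, "unknown"),
                                "observed_t": r.observed_t,
                                "p_corrected": r.p_corrected,
                            }
                        )
        edge_tests = pd.DataFrame(test_rows)

        inter_rows = []
        if config.run_interactions and config.interactions and len(edges):
            for score_name, edge_name in config.interactions:
                for contrast in config.contrasts:
                    stage = f"interaction[{score_name}~{edge_name}:{contrast}]"
                    keep, labels = _contrast_labels(pheno["group"], contrast)
                    g01 = (labels == "A").astype(float)
                    score = pheno.loc[keep, score_name].to_numpy(float)
                    edge = edges.iloc[np.flatnonzero(keep)][edge_name].to_numpy(float)
                    for model in config.models:
                        if model == "corrected":
                            y = huber_residualize(score, covs[keep], config.huber)[0]
                            x = huber_residualize(edge, covs[keep], config.huber)[0]
                        else:
                            y, x = score, edge
                        res = manly_permutation_pvalues(
                            y, x, g01,
                            PermutationSettings(n_permutations=config.n_permutations,
                                                seed=int(next(seed_stream))),
                            config.huber,
                            score_name=score_name, edge_key=edge_name, model=model,
                        )
                        inter_rows.append(
                            {
                                "score": score_name,
                                "edge": edge_name,
                                "network_pair": pair_of.get(edge_name, "unknown"),
                                "contrast": contrast,
                                "model": model,
                                "beta_interaction": res.beta_interaction,
                                "p_perm": res.p_perm,
                            }
                        )
        interactions = pd.DataFrame(inter_rows)

        # --- cohort statistics -------------------------------------------
        stage = "cohort-stats"
        summary = group_summary_table(pheno) if len(pheno) else pd.DataFrame()

        stage = "report"
        provenance = {
            "package_version": __version__,
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "n_subjects_retained": len(subjects),
        }
        result = RunResult(
            config=config, qc=qc, lesion_flags=lesion_flags, edges=edges,
            edge_networks=edge_networks, edge_tests=edge_tests,
            interactions=interactions, summary=summary, phenotypes=pheno,
            provenance=provenance,
        )
        if config.out_dir:
            _write_result(result, Path(config.out_dir))
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _write_result(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.qc.to_csv(outdir / "qc.tsv", sep="\t", index=False)
    result.lesion_flags.to_csv(outdir / "lesion_flags.tsv", sep="\t", index=False)
    result.edges.to_csv(outdir / "edges.tsv", sep="\t")
    result.edge_networks.to_csv(outdir / "edge_networks.tsv", sep="\t", index=False)
    result.edge_tests.to_csv(outdir / "edge_tests.tsv", sep="\t", index=False)
    result.interactions.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
    result.summary.to_csv(outdir / "group_summary.tsv", sep="\t", index=False)
    result.phenotypes.to_csv(outdir / "participants.tsv", sep="\t", index=False)
    (outdir / "provenance.json").write_text(json.dumps(result.provenance, indent=2))
    log.info("results written to %s", outdir)
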