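"""End-to-end orchestration: cohort -> graphs -> partitions -> SI -> stats.

The pipeline mirrors the study workflow: per subject and scan condition
a binary network is built at conserved density S and partitioned by
multi-restart modularity maximization; reference ROIs are refined into
study-specific ROIs by pooled-SI argmax; per-subject global and regional
consistency are summarized and compared across conditions with the
repeated-measures model and within-subject permutation tests.  All
outputs are plain text, and a manifest records every parameter and seed
so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .cohort import (
    Cohort,
    CohortSpec,
    generate_cohort,
    generate_covariates,
    generate_vas_responses,
)
from .community import Partition, best_partition
from .network import DEFAULT_S, binarize_by_density, correlation_matrix
from .refine import ROIAtlas, assign_by_argmax, exclude_rois, pooled_si_maps, rois_from_labels
from .si import SIMap, subject_si_map
from .stats import (
    ConditionContrastModel,
    ConditionContrastResults,
    PermutationResult,
    global_consistency,
    minmax_scale,
    permutation_test,
    regional_consistency,
)
from .vas import VASClassification, classify_differences

__all__ = ["RunConfig", "StudyResult", "run_pipeline", "write_cohort", "load_manifest"]

logger = logging.getLogger("netsi")

VAS_QUESTIONS = (("Imagine", 5.0), ("4 Minutes", 5.0), ("Difficulty", 10.0))


@dataclass
class RunConfig:
    """Everything needed to reproduce one full analysis run.

    Exactly one of ``cohort`` (synthetic mode) or ``manifest`` (file
    mode) must be set.  Defaults follow the study where it states them:
    density S = 2.5 and 100 modularity restarts per network.
    """

    out_dir: Path | str
    cohort: CohortSpec | None = None
    manifest: Path | str | None = None
    s: float = DEFAULT_S
    n_runs: int = 100
    n_perm: int = 1000
    seed: int = 0
    edge_mode: str = "positive"
    exclude_roi_ids: tuple[int, ...] = ()
    alpha: float = 0.05
    regional_roi_ids: tuple[int, ...] | None = None
    threads: int = 1  # results are independent of this value

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.manifest is None):
            raise ValueError("set exactly one of cohort (synthetic) or manifest")


@dataclass
class StudyResult:
    """Bundle of every cohort-level product of one pipeline run."""

    config: RunConfig
    atlas: ROIAtlas
    partitions: dict[tuple[int, str], Partition]
    consistency: pd.DataFrame
    comparisons: dict[str, ConditionContrastResults]
    permutations: dict[tuple[int, str, str], PermutationResult]
    vas: dict[str, VASClassification] = field(default_factory=dict)
    out_dir: Path | None = None


# ---------------------------------------------------------------------------
# cohort serialization
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, out_dir: Path | str, seed: int | None = None) -> Path:
    """Write a synthetic cohort to disk and return the manifest path.

    Emits time-series TSVs, ground-truth partition TSVs, the template
    ROI map, synthetic covariates and VAS tables, and a manifest listing
    them all.
    """
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    (out / "ground_truth").mkdir(exist_ok=True)
    spec = cohort.spec
    seed = spec.seed if seed is None else seed
    subjects = []
    for subj in cohort.subjects():
        entry: dict = {"id": int(subj), "conditions": {}}
        for cond in spec.condition_names:
            rel = f"timeseries/sub{subj:03d}_{cond}.tsv"
            nio.write_timeseries(cohort.timeseries[(subj, cond)], out / rel)
            entry["conditions"][cond] = rel
            nio.write_partition(
                cohort.ground_truth.planted[(subj, cond)],
                out / f"ground_truth/sub{subj:03d}_{cond}.tsv",
            )
        subjects.append(entry)
    nio.write_roi_map(cohort.ground_truth.template.labels, out / "reference_rois.tsv")
    generate_covariates(spec.n_subjects, seed=seed + 1).to_csv(
        out / "covariates.csv", index=False
    )
    vas_frames = [
        generate_vas_responses(spec.n_subjects, shift, seed=seed + 2 + i, question=q)
        for i, (q, shift) in enumerate(VAS_QUESTIONS)
    ]
    pd.concat(vas_frames, ignore_index=True).to_csv(out / "vas.csv", index=False)
    manifest = {
        "n_nodes": spec.n_nodes,
        "conditions": list(spec.condition_names),
        "roi_map": "reference_rois.tsv",
        "covariates": "covariates.csv",
        "vas": "vas.csv",
        "subjects": subjects,
    }
    path = out / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def load_manifest(path: Path | str):
    """Load a cohort manifest: time series, ROI labels, covariates, VAS."""
    path = Path(path)
    base = path.parent
    man = yaml.safe_load(path.read_text())
    data: dict[tuple[int, str], np.ndarray] = {}
    for entry in man["subjects"]:
        for cond, rel in entry["conditions"].items():
            data[(int(entry["id"]), cond)] = nio.read_timeseries(base / rel)
    roi_labels = nio.read_roi_map(base / man["roi_map"])
    covariates = (
        pd.read_csv(base / man["covariates"]) if man.get("covariates") else None
    )
    vas = pd.read_csv(base / man["vas"]) if man.get("vas") else None
    return data, roi_labels, covariates, vas, tuple(man["conditions"])


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def _stage_done(name: str, t0: float) -> None:
    logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)


def run_pipeline(config: RunConfig) -> StudyResult:
    """Run the full analysis and write all products under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = _stage("inputs")
    if config.cohort is not None:
        cohort = generate_cohort(config.cohort)
        data = cohort.timeseries
        roi_labels = cohort.ground_truth.template.labels
        conditions = cohort.spec.condition_names
        covariates = generate_covariates(cohort.spec.n_subjects, seed=config.seed + 1)
        vas_table = pd.concat(
            [
                generate_vas_responses(
                    cohort.spec.n_subjects, shift, seed=config.seed + 2 + i, question=q
                )
                for i, (q, shift) in enumerate(VAS_QUESTIONS)
            ],
            ignore_index=True,
        )
    else:
        data, roi_labels, covariates, vas_table, conditions = load_manifest(
            config.manifest
        )
    subjects = sorted({s for s, _ in data})
    _stage_done("inputs", t0)

    t0 = _stage("networks+partitions")
    (out / "networks").mkdir(exist_ok=True)
    (out / "partitions").mkdir(exist_ok=True)
    partitions: dict[tuple[int, str], Partition] = {}
    net_rows = []
    for subj in subjects:
        for ci, cond in enumerate(conditions):
            ts = data[(subj, cond)]
            adj = binarize_by_density(correlation_matrix(ts), config.s, config.edge_mode)
            tag = f"sub{subj:03d}_{cond}"
            nio.write_edgelist(adj, out / "networks" / f"{tag}.edges.tsv")
            part = best_partition(
                adj,
                n_runs=config.n_runs,
                seed=config.seed + 1000 * subj + 100000 * ci,
                keep_log=True,
            )
            partitions[(subj, cond)] = part
            nio.write_partition(part, out / "partitions" / f"{tag}.tsv")
            net_rows.append(
                {
                    "subject_id": subj,
                    "condition": cond,
                    "n_nodes": adj.n,
                    "n_edges": adj.n_edges,
                    "avg_degree": adj.avg_degree,
                    "achieved_s": adj.achieved_s,
                    "q": part.q,
                    "n_communities": part.n_communities,
                    "chosen_run": part.chosen_run,
                }
            )
    pd.DataFrame(net_rows).to_csv(out / "network_summary.csv", index=False)
    _stage_done("networks+partitions", t0)

    t0 = _stage("roi refinement")
    reference_rois = rois_from_labels(roi_labels)
    pooled = pooled_si_maps(reference_rois, list(partitions.values()))
    atlas = assign_by_argmax(pooled)
    if config.exclude_roi_ids:
        atlas = exclude_rois(atlas, config.exclude_roi_ids)
    nio.write_roi_map(atlas.assignment, out / "study_specific_rois.tsv")
    before = {r.roi_id: r.size for r in reference_rois}
    pd.DataFrame(
        [
            {
                "roi_id": rid,
                "n_nodes_reference": before.get(rid, 0),
                "n_nodes_refined": cnt,
                "excluded": rid in atlas.excluded_roi_ids,
            }
            for rid, cnt in atlas.node_counts().items()
        ]
    ).to_csv(out / "refinement_report.csv", index=False)
    _stage_done("roi refinement", t0)

    t0 = _stage("consistency measures")
    analyzable = atlas.analyzable_rois()
    rows = []
    scaled_maps: dict[tuple[int, str], dict[int, SIMap]] = {}
    for subj in subjects:
        for cond in conditions:
            part = partitions[(subj, cond)]
            maps = {roi.roi_id: subject_si_map(roi, part) for roi in analyzable}
            rows.append(
                {
                    "subject_id": subj,
                    "condition": cond,
                    "measure": "global",
                    "value": global_consistency(maps),
                }
            )
            scaled = minmax_scale(maps)
            scaled_maps[(subj, cond)] = scaled
            for roi in analyzable:
                rows.append(
                    {
                        "subject_id": subj,
                        "condition": cond,
                        "measure": f"roi{roi.roi_id}",
                        "value": regional_consistency(scaled[roi.roi_id], roi),
                    }
                )
    consistency = pd.DataFrame(rows)
    if covariates is not None:
        consistency = consistency.merge(covariates, on="subject_id", how="left")
    consistency.to_csv(out / "consistency.csv", index=False)
    _stage_done("consistency measures", t0)

    t0 = _stage("condition contrasts")
    covariate_names = (
        tuple(c for c in ("age", "sex", "race") if c in consistency.columns)
        if covariates is not None
        else ()
    )
    comparisons: dict[str, ConditionContrastResults] = {}
    (out / "comparisons").mkdir(exist_ok=True)
    for measure in consistency["measure"].unique():
        model = ConditionContrastModel.from_dataframe(
            consistency[consistency["measure"] == measure],
            covariates=covariate_names,
            conditions=conditions,
        )
        res = model.fit(alpha=config.alpha)
        comparisons[measure] = res
        res.to_frame().to_csv(out / "comparisons" / f"{measure}.csv", index=False)
        (out / "comparisons" / f"{measure}.txt").write_text(res.summary() + "\n")
    _stage_done("condition contrasts", t0)

    t0 = _stage("permutation tests")
    perm_ids = (
        config.regional_roi_ids
        if config.regional_roi_ids is not None
        else tuple(r.roi_id for r in analyzable)
    )
    permutations: dict[tuple[int, str, str], PermutationResult] = {}
    perm_rows = []
    for roi in analyzable:
        if roi.roi_id not in perm_ids:
            continue
        for ia in range(len(conditions)):
            for ib in range(ia + 1, len(conditions)):
                ca, cb = conditions[ia], conditions[ib]
                maps_a = {s: scaled_maps[(s, ca)][roi.roi_id] for s in subjects}
                maps_b = {s: scaled_maps[(s, cb)][roi.roi_id] for s in subjects}
                res = permutation_test(
                    maps_a,
                    maps_b,
                    roi,
                    n_perm=config.n_perm,
                    seed=config.seed + 7919 * roi.roi_id + 31 * ia + ib,
                )
                permutations[(roi.roi_id, ca, cb)] = res
                perm_rows.append(
                    {
                        "roi_id": roi.roi_id,
                        "comparison": f"{ca} vs. {cb}",
                        "observed": res.observed,
                        "p_value": res.p_value,
                        "n_perm": res.n_perm,
                    }
                )
    pd.DataFrame(perm_rows).to_csv(out / "permutation_tests.csv", index=False)
    _stage_done("permutation tests", t0)

    vas_results: dict[str, VASClassification] = {}
    if vas_table is not None:
        t0 = _stage("vas")
        questions = (
            vas_table["question"].unique() if "question" in vas_table else [None]
        )
        frames = []
        for q in questions:
            cls = classify_differences(vas_table, question=q)
            vas_results[q or "all"] = cls
            frames.append(cls.to_frame())
        pd.concat(frames, ignore_index=True).to_csv(out / "vas_table.csv", index=False)
        _stage_done("vas", t0)

    manifest = {
        "package": "netsi",
        "parameters": {
            "s": config.s,
            "n_runs": config.n_runs,
            "n_perm": config.n_perm,
            "seed": config.seed,
            "edge_mode": config.edge_mode,
            "alpha": config.alpha,
            "exclude_roi_ids": list(config.exclude_roi_ids),
            "conditions": list(conditions),
        },
        "cohort_spec": (
            {
                "n_subjects": config.cohort.n_subjects,
                "n_nodes": config.cohort.n_nodes,
                "community_sizes": list(config.cohort.community_sizes),
                "conditions": [list(c) for c in config.cohort.conditions],
                "within_r": config.cohort.within_r,
                "between_r": config.cohort.between_r,
                "n_timepoints": config.cohort.n_timepoints,
                "noise_sd": config.cohort.noise_sd,
                "seed": config.cohort.seed,
            }
            if config.cohort is not None
            else None
        ),
        "input_manifest": str(config.manifest) if config.manifest else None,
        "input_checksums": {
            f"sub{s:03d}_{c}": hashlib.md5(
                np.ascontiguousarray(data[(s, c)]).tobytes()
            ).hexdigest()
            for s in subjects
            for c in conditions
        },
    }
    (out / "run_manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))

    return StudyResult(
        config=config,
        atlas=atlas,
        partitions=partitions,
        consistency=consistency,
        comparisons=comparisons,
        permutations=permutations,
        vas=vas_results,
        out_dir=out,
    )
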