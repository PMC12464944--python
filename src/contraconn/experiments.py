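"""End-to-end experiment wiring.

Seven experiments are supported, mirroring the stages of a
contralesional-connectome study:

``identity``     patient-vs-control SVM on right-hemisphere RRCz
``idh``          IDH genotype (mutant vs wildtype) SVM among patients
``grade``        WHO grade (high vs low) SVM among patients
``size``         relative tumor volume (median split) SVM among patients
``roi_lesion``   per-ROI lesion-presence SVMs with the two-stage MCC screen
``cluster_map``  silhouette-selected k-means on patient RRCz, linked to
                 lesion overlap / difference maps and voxelwise Barnard tests
``homotopic``    Spearman association between per-ROI model MCC and
                 control-cohort homotopic (vs non-homotopic) connectivity

Each runner takes a cohort (synthetic or loaded from files), returns a
plain-dict report, and draws every random number from the seed it is
given.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import clustering, connectome, inference, lesion_mapping, ml_engine, stats_core
from .synthetic_cohort import SyntheticCohort

__all__ = [
    "ExperimentSpec",
    "median_split",
    "run_experiment",
    "run_identity",
    "run_tumor_characteristic",
    "run_roi_lesion",
    "run_cluster_map",
    "run_homotopic",
]

EXPERIMENT_NAMES = ("identity", "idh", "grade", "size", "roi_lesion",
                    "cluster_map", "homotopic")


@dataclass(frozen=True)
class ExperimentSpec:
    """One experiment: which pipeline, on which cohort, with which settings."""

    name: str
    cohort: SyntheticCohort
    config: ml_engine.CVConfig = field(default_factory=ml_engine.CVConfig)
    n_repeats: int = 100
    n_permutations: int = 1000
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENT_NAMES:
            raise ValueError(f"unknown experiment {self.name!r}; "
                             f"choose from {EXPERIMENT_NAMES}")


def median_split(volumes) -> np.ndarray:
    """Label lesions 'large' (> median) or 'small' (<= median, ties small)."""
    volumes = np.asarray(volumes, dtype=float)
    if volumes.size < 2:
        raise ValueError("need at least 2 patients")
    med = np.median(volumes)
    return np.where(volumes > med, "large", "small")


def _perm_summary(results: Mapping[str, inference.PermutationResult]) -> dict[str, Any]:
    out = {}
    for m, res in results.items():
        valid = res.null[~np.isnan(res.null)]
        out[m] = {
            "observed": res.observed,
            "null_mean": float(valid.mean()) if valid.size else float("nan"),
            "null_sd": float(valid.std(ddof=1)) if valid.size > 1 else float("nan"),
            "r": res.r,
            "n": res.n,
            "p": res.p,
        }
    return out


def run_identity(cohort: SyntheticCohort, config: ml_engine.CVConfig,
                 n_repeats: int = 100, n_permutations: int = 1000,
                 seed: int = 0) -> dict[str, Any]:
    """Patient-vs-control classification with repeats and a permutation null."""
    X = connectome.rrcz_normalize(cohort.edges)
    y = cohort.labels
    rep = ml_engine.repeat_evaluate(X, y, config, n_repeats=n_repeats)
    perm = inference.permutation_null(X, y, config, n_iter=n_permutations, seed=seed)
    return {
        "experiment": "identity",
        "n_subjects": len(y),
        "n_patients": int(y.sum()),
        "n_edges": X.shape[1],
        "repeat_mean": {m: rep.mean(m) for m in ("accuracy", "precision", "recall", "mcc")},
        "repeat_sd": {m: rep.sd(m) for m in ("accuracy", "precision", "recall", "mcc")},
        "permutation": _perm_summary(perm),
        "seed": seed,
    }


def _patient_labels(cohort: SyntheticCohort, target: str) -> np.ndarray:
    patients = [cohort.subjects[i] for i in cohort.patient_index]
    if target == "idh":
        return np.array([1 if s.idh == "mutant" else 0 for s in patients])
    if target == "grade":
        return np.array([1 if s.who_grade == "high" else 0 for s in patients])
    if target == "size":
        vols = [s.lesion_volume for s in patients]
        return (median_split(vols) == "large").astype(int)
    raise ValueError(f"unknown tumor characteristic {target!r}")


def run_tumor_characteristic(cohort: SyntheticCohort, target: str,
                             config: ml_engine.CVConfig | None = None,
                             n_repeats: int = 100, n_permutations: int = 1000,
                             seed: int = 0) -> dict[str, Any]:
    """IDH / grade / relative-size classification among patients (MRMR on)."""
    if config is None:
        config = ml_engine.CVConfig(mrmr_threshold=0.05, seed=seed)
    X = connectome.rrcz_normalize(cohort.edges[cohort.patient_index])
    y = _patient_labels(cohort, target)
    rep = ml_engine.repeat_evaluate(X, y, config, n_repeats=n_repeats)
    perm = inference.permutation_null(X, y, config, n_iter=n_permutations, seed=seed)
    return {
        "experiment": target,
        "n_patients": len(y),
        "class_counts": dict(zip(*map(list, np.unique(y, return_counts=True)))),
        "repeat_mean": {m: rep.mean(m) for m in ("accuracy", "precision", "recall", "mcc")},
        "permutation": _perm_summary(perm),
        "seed": seed,
    }


def roi_datasets(cohort: SyntheticCohort, presence_threshold: float = 0.01,
                 min_patient_fraction: float = 0.2):
    """Per-ROI (patient RRCz, lesion-presence labels) for suprathreshold ROIs."""
    table = lesion_mapping.intersection_table(list(cohort.masks), cohort.atlas,
                                              threshold=presence_threshold)
    included = lesion_mapping.select_rois(table.presence, min_patient_fraction,
                                          left_ids=table.left_ids)
    X = connectome.rrcz_normalize(cohort.edges[cohort.patient_index])
    presence = table.presence
    data = {int(roi): (X, presence[:, int(roi) - 1]) for roi in included}
    return data, table, included


def run_roi_lesion(cohort: SyntheticCohort, config: ml_engine.CVConfig | None = None,
                   stage1_iter: int = 100, stage2_iter: int = 1000,
                   seed: int = 0, mrmr_threshold: float = 0.05,
                   min_patient_fraction: float = 0.2) -> dict[str, Any]:
    """Regional lesion-presence models with the two-stage MCC screen.

    ROI-level models use inner LOOCV and per-fold MRMR; ROIs enter only if
    at least 20% of patients have a lesion present (>= 1% intersection).
    """
    if config is None:
        config = ml_engine.CVConfig(inner="loocv", mrmr_threshold=mrmr_threshold,
                                    seed=seed)
    data, table, included = roi_datasets(cohort, min_patient_fraction=min_patient_fraction)
    screen = inference.two_stage_screen(data, config, stage1_iter=stage1_iter,
                                        stage2_iter=stage2_iter, seed=seed)
    rois = {
        roi: {
            "observed_mcc": res.observed_mcc,
            "stage1_p": res.stage1_p,
            "candidate": res.candidate,
            "stage2": _perm_summary(res.stage2) if res.stage2 else None,
            "significant": res.significant,
        }
        for roi, res in screen.items()
    }
    return {
        "experiment": "roi_lesion",
        "n_included_rois": len(included),
        "included_rois": [int(r) for r in included],
        "rois": rois,
        "significant_rois": [roi for roi, r in screen.items() if r.significant],
        "seed": seed,
    }


def run_cluster_map(cohort: SyntheticCohort, k_range=range(2, 11),
                    seed: int = 0, alpha: float = 0.05) -> dict[str, Any]:
    """Cluster patients on RRCz and contrast the clusters' lesion anatomy."""
    X = connectome.rrcz_normalize(cohort.edges[cohort.patient_index])
    ks = [k for k in k_range if 2 <= k <= len(X) - 1]
    k_star, curve = clustering.silhouette_select_k(X, k_range=ks, seed=seed)
    result = clustering.cluster_patients(X, k_star, seed=seed)
    masks = list(cohort.masks)
    maps = {}
    for c in range(k_star):
        members = [masks[i] for i in np.flatnonzero(result.assignments == c)]
        maps[c] = lesion_mapping.overlap_map(members)
    report: dict[str, Any] = {
        "experiment": "cluster_map",
        "k": k_star,
        "silhouette": curve,
        "cluster_sizes": np.bincount(result.assignments, minlength=k_star).tolist(),
        "assignments": result.assignments.tolist(),
        "seed": seed,
    }
    if k_star == 2:
        diff = lesion_mapping.normalized_difference_map(maps[1], maps[0])
        p_map, sig = lesion_mapping.voxelwise_barnard(masks, result.assignments,
                                                      alpha=alpha)
        report["difference_map_range"] = [float(diff.min()), float(diff.max())]
        report["n_significant_voxels"] = int(sig.sum())
        report["_maps"] = {"overlap": maps, "difference": diff, "p": p_map}
    else:
        report["_maps"] = {"overlap": maps}
    return report


def run_homotopic(cohort: SyntheticCohort, config: ml_engine.CVConfig | None = None,
                  seed: int = 0, mrmr_threshold: float = 0.05,
                  min_patient_fraction: float = 0.2) -> dict[str, Any]:
    """Does control homotopic coupling predict where lesions are detectable?

    For each suprathreshold left ROI, fit the lesion-presence model once
    (inner LOOCV) and record its MCC; then correlate MCC with the
    control-cohort mean homotopic FC of that ROI (Spearman), and with the
    mean non-homotopic FC as a specificity control.
    """
    if config is None:
        config = ml_engine.CVConfig(inner="loocv", mrmr_threshold=mrmr_threshold,
                                    seed=seed)
    data, table, included = roi_datasets(cohort, min_patient_fraction=min_patient_fraction)
    mccs = []
    for roi in included:
        X, y_roi = data[int(roi)]
        pv = ml_engine.nested_cv_predict(X, y_roi, config)
        mccs.append(ml_engine.evaluate_predictions(y_roi, pv.predictions).mcc)
    mccs = np.asarray(mccs)
    controls_ih = cohort.interhemispheric[cohort.control_index]
    hom = connectome.homotopic_mean_fc(controls_ih, cohort.atlas, left_rois=included)
    nonhom = connectome.nonhomotopic_mean_fc(controls_ih, cohort.atlas, left_rois=included)
    rho_h, p_h = stats_core.spearman(mccs, hom)
    rho_n, p_n = stats_core.spearman(mccs, nonhom)
    return {
        "experiment": "homotopic",
        "included_rois": [int(r) for r in included],
        "mcc": mccs.tolist(),
        "homotopic_fc": hom.tolist(),
        "nonhomotopic_fc": nonhom.tolist(),
        "spearman_homotopic": {"rho": rho_h, "p": p_h},
        "spearman_nonhomotopic": {"rho": rho_n, "p": p_n},
        "seed": seed,
    }


def run_experiment(spec: ExperimentSpec) -> dict[str, Any]:
    """Dispatch an ExperimentSpec to its pipeline; optionally write JSON."""
    if spec.name == "identity":
        report = run_identity(spec.cohort, spec.config, spec.n_repeats,
                              spec.n_permutations, spec.seed)
    elif spec.name in ("idh", "grade", "size"):
        report = run_tumor_characteristic(spec.cohort, spec.name, spec.config,
                                          spec.n_repeats, spec.n_permutations,
                                          spec.seed)
    elif spec.name == "roi_lesion":
        report = run_roi_lesion(spec.cohort, spec.config,
                                stage2_iter=spec.n_permutations, seed=spec.seed)
    elif spec.name == "cluster_map":
        report = run_cluster_map(spec.cohort, seed=spec.seed)
    elif spec.name == "homotopic":
        report = run_homotopic(spec.cohort, spec.config, seed=spec.seed)
    else:  # pragma: no cover - guarded by ExperimentSpec
        raise ValueError(spec.name)
    if spec.output_dir is not None:
        out = Path(spec.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        serializable = {k: v for k, v in report.items() if not k.startswith("_")}
        (out / f"{spec.name}_report.json").write_text(
            json.dumps(serializable, indent=2, default=float))
    return report
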