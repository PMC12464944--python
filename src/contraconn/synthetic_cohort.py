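"""Synthetic atlases, lesion masks and patient/control cohorts.

The generator emulates the structure of a contralesional-connectome study:
a homotopically paired parcellation (N parcels per hemisphere), binary
lesion masks for left-hemisphere gliomas, and Fisher-z right-hemisphere
edge vectors for patients and controls.  Group effects are injected as a
shift ``delta`` on the edges mapped to each patient's lesioned left ROIs,
optionally scaled by that ROI's homotopic coupling in controls and by an
IDH-genotype ratio, so that every downstream stage (classification,
permutation nulls, ROI screens, clustering, homotopic analysis) can be
exercised with known ground truth.

Default study conditions mirror the emulated design: 48 patients vs 107
controls; 25 IDH-mutant / 23 wildtype and 32 high- / 16 low-grade tumors
at n = 48 (scaled proportionally otherwise); lesion centers drawn
uniformly from a "perisylvian" middle band of left ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Atlas",
    "LesionMask",
    "SubjectRecord",
    "EffectConfig",
    "SyntheticCohort",
    "generate_atlas",
    "generate_lesion_mask",
    "generate_cohort",
    "default_effect_map",
]


@dataclass(frozen=True)
class Atlas:
    """Homotopically paired parcellation on an integer label image.

    ROI ids are 1..N (left hemisphere) and N+1..2N (right hemisphere);
    ``homotopic_pair`` maps left id i -> right id i+N, realized as
    mirror-image parcels across the mid-sagittal (x) plane.  0 is
    background.
    """

    label_image: np.ndarray
    n_per_hemisphere: int
    roi_names: tuple[str, ...] | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        n = self.n_per_hemisphere
        present = set(np.unique(self.label_image)) - {0}
        if present != set(range(1, 2 * n + 1)):
            raise ValueError("label image must contain every ROI id 1..2N at least once")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.label_image.shape

    @property
    def left_ids(self) -> np.ndarray:
        return np.arange(1, self.n_per_hemisphere + 1)

    @property
    def right_ids(self) -> np.ndarray:
        return np.arange(self.n_per_hemisphere + 1, 2 * self.n_per_hemisphere + 1)

    @property
    def homotopic_pair(self) -> dict[int, int]:
        return {int(i): int(i + self.n_per_hemisphere) for i in self.left_ids}

    def hemisphere(self, roi: int) -> str:
        if 1 <= roi <= self.n_per_hemisphere:
            return "left"
        if self.n_per_hemisphere < roi <= 2 * self.n_per_hemisphere:
            return "right"
        raise KeyError(f"unknown ROI id {roi}")

    def roi_mask(self, roi: int) -> np.ndarray:
        self.hemisphere(roi)
        return self.label_image == roi

    def roi_volume(self, roi: int) -> int:
        return int(self.roi_mask(roi).sum())

    def left_roi_indices(self, left_rois=None) -> np.ndarray:
        """0-based indices into left-ROI order for the given left ids."""
        if left_rois is None:
            return np.arange(self.n_per_hemisphere)
        ids = np.asarray(list(left_rois), dtype=int)
        if np.any(ids < 1) or np.any(ids > self.n_per_hemisphere):
            raise KeyError("left ROI ids must be in 1..N")
        return ids - 1


@dataclass(frozen=True)
class LesionMask:
    """Binary lesion volume on the atlas grid."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        vals = np.unique(self.voxels)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("lesion mask must be binary")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def volume(self) -> int:
        return int(self.voxels.sum())


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str  # "patient" | "control"
    age: float
    sex: str  # "M" | "F"
    idh: str = "NA"  # "mutant" | "wildtype" | "NA"
    who_grade: str = "NA"  # "high" | "low" | "NA"
    lesion_volume: int = 0
    lesion_mask_ref: int | None = None  # index into the cohort mask list

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"bad group {self.group!r}")
        if self.group == "control" and (self.idh != "NA" or self.who_grade != "NA"
                                        or self.lesion_mask_ref is not None):
            raise ValueError("controls carry no tumor annotations or lesion mask")


@dataclass(frozen=True)
class EffectConfig:
    """How much, and where, patient connectivity departs from controls.

    delta            additive shift (Fisher-z units) on targeted edges
    effect_map       left ROI id -> array of right-hemisphere edge indices;
                     None selects :func:`default_effect_map` (the star of
                     the lesioned ROI's homotopic partner plus the clique
                     among the core-network partners)
    homotopic_scaling  multiply delta by the lesioned ROI's control
                     homotopic coupling
    idh_delta_ratio  extra multiplier for IDH-mutant patients
    noise_sd         sd of i.i.d. edge noise (Fisher-z units)
    seed             master seed for the cohort draw
    """

    delta: float = 0.0
    effect_map: Mapping[int, np.ndarray] | None = None
    homotopic_scaling: bool = True
    idh_delta_ratio: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: metadata, edges, masks and ground truth."""

    atlas: Atlas
    subjects: tuple[SubjectRecord, ...]
    edges: np.ndarray  # (n_subjects, M) raw Fisher-z right-hemisphere edges
    masks: tuple[LesionMask, ...]  # one per patient, indexed by lesion_mask_ref
    interhemispheric: np.ndarray  # (n_subjects, N, N) left x right FC block
    pair_coupling: np.ndarray  # ground-truth homotopic coupling per left ROI
    lesion_centers: tuple[int, ...]  # per-patient sampled center left ROI

    @property
    def labels(self) -> np.ndarray:
        """1 for patients, 0 for controls."""
        return np.array([s.group == "patient" for s in self.subjects], dtype=int)

    @property
    def patient_index(self) -> np.ndarray:
        return np.flatnonzero(self.labels)

    @property
    def control_index(self) -> np.ndarray:
        return np.flatnonzero(1 - self.labels)


def generate_atlas(
    n_per_hemisphere: int,
    grid_shape: Sequence[int] = (24, 24, 24),
    seed: int = 0,
) -> Atlas:
    """Random mirror-symmetric parcellation of a voxel grid.

    The left half of the first (x) axis is partitioned into N parcels by
    nearest-seed (Voronoi) assignment around N distinct seed voxels; the
    right half is its mirror image, so homotopic pairs are true
    mirror-image parcels.  Deterministic given the seed.
    """
    if n_per_hemisphere < 2:
        raise ValueError("need at least 2 ROIs per hemisphere")
    grid_shape = tuple(int(g) for g in grid_shape)
    if len(grid_shape) != 3:
        raise ValueError("grid_shape must be 3-D")
    nx = grid_shape[0]
    half_nx = nx // 2
    n_left_voxels = half_nx * grid_shape[1] * grid_shape[2]
    if n_left_voxels < n_per_hemisphere:
        raise ValueError(
            f"grid {grid_shape} too small for {n_per_hemisphere} parcels per hemisphere"
        )
    rng = np.random.default_rng(seed)
    coords = np.indices((half_nx,) + grid_shape[1:]).reshape(3, -1).T
    seed_rows = rng.choice(len(coords), size=n_per_hemisphere, replace=False)
    seeds = coords[np.sort(seed_rows)].astype(float)
    # nearest-seed assignment; ties resolved toward the lower ROI id
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1) + 1
    labels = np.zeros(grid_shape, dtype=np.int32)
    left = assign.reshape((half_nx,) + grid_shape[1:])
    labels[:half_nx] = left
    right = np.flip(left, axis=0)
    labels[nx - half_nx:] = np.where(right > 0, right + n_per_hemisphere, 0)
    return Atlas(label_image=labels, n_per_hemisphere=n_per_hemisphere)


def generate_lesion_mask(
    atlas: Atlas,
    center_roi: int,
    radius: float,
    seed: int = 0,
) -> LesionMask:
    """Spherical lesion around a random voxel of a left-hemisphere ROI."""
    if atlas.hemisphere(center_roi) != "left":
        raise ValueError(f"lesion center ROI {center_roi} must be left-hemisphere")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    rng = np.random.default_rng(seed)
    roi_voxels = np.argwhere(atlas.roi_mask(center_roi))
    center = roi_voxels[rng.integers(len(roi_voxels))]
    grids = np.indices(atlas.grid_shape)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    mask = (d2 <= radius**2).astype(np.int8)
    return LesionMask(voxels=mask)


def _edge_idx(i: int, j: int, n: int) -> int:
    i, j = (i, j) if i < j else (j, i)
    return i * n - i * (i + 1) // 2 + (j - i - 1)


def core_network(atlas: Atlas) -> list[int]:
    """Default "perisylvian" band of left ROI ids (middle half of the ids).

    Used both as the default lesion-center distribution and as the shared
    functional network whose contralesional homologues reorganize
    together.
    """
    n = atlas.n_per_hemisphere
    lo, hi = n // 4, n - n // 4
    return list(range(lo + 1, hi + 1))


def default_effect_map(atlas: Atlas, network_rois: Sequence[int] | None = None) -> dict[int, np.ndarray]:
    """Right-hemisphere edges affected when a given left ROI is lesioned.

    A lesion in left ROI r perturbs (i) the edges incident to r's
    homotopic partner — the location-specific signature — and (ii) the
    edges among the homotopic partners of the core network
    (:func:`core_network` by default) — a coordinated, shared
    reorganization of the contralesional homologue network, so that
    lesions at different sites within the network still move a common
    set of edges.  Edge indices refer to the row-major upper triangle
    over the N right ROIs (0-based right-ROI order).
    """
    n = atlas.n_per_hemisphere
    if network_rois is None:
        network_rois = core_network(atlas)
    partners = [atlas.homotopic_pair[int(r)] - n - 1 for r in network_rois]
    clique = {_edge_idx(a, b, n) for a in partners for b in partners if a < b}
    out: dict[int, np.ndarray] = {}
    for left_id in atlas.left_ids:
        j = atlas.homotopic_pair[int(left_id)] - n - 1  # 0-based right index
        star = {_edge_idx(j, k, n) for k in range(n) if k != j}
        out[int(left_id)] = np.array(sorted(star | clique), dtype=int)
    return out


def _proportional_counts(n: int, ref: tuple[int, int]) -> tuple[int, int]:
    a = int(round(n * ref[0] / sum(ref)))
    return a, n - a


def generate_cohort(
    atlas: Atlas,
    n_patients: int,
    n_controls: int,
    effect: EffectConfig,
    *,
    idh_counts: tuple[int, int] | None = None,
    grade_counts: tuple[int, int] | None = None,
    lesion_center_choices: Sequence[int] | None = None,
    lesion_radius_range: tuple[int, int] | None = None,
    presence_threshold: float = 0.01,
    subject_intercept_sd: float = 0.1,
    pair_coupling_range: tuple[float, float] = (0.3, 1.2),
) -> SyntheticCohort:
    """Draw a full synthetic cohort with a known injected group effect.

    Controls' raw right-hemisphere edges are Normal(mu_e, noise_sd^2),
    i.i.d. across edges, plus a per-subject intercept.  Each patient gets
    a spherical lesion centered on a sampled left ROI; edges in
    ``effect.effect_map`` of every lesion-present ROI (intersection
    fraction >= ``presence_threshold``) are shifted by delta, scaled by
    the control homotopic coupling of that ROI when ``homotopic_scaling``
    and by ``idh_delta_ratio`` for IDH-mutant patients.

    ``idh_counts``/``grade_counts`` fix the (mutant, wildtype) and
    (high, low) patient counts exactly; defaults scale the emulated
    25/23 and 32/16 design to ``n_patients``.
    """
    if n_patients < 2 or n_controls < 2:
        raise ValueError("need at least 2 patients and 2 controls")
    n = atlas.n_per_hemisphere
    m = n * (n - 1) // 2
    effect_map = effect.effect_map
    if effect_map is None:
        effect_map = default_effect_map(atlas)
    if effect.delta > 0 and not any(len(v) for v in effect_map.values()):
        raise ValueError("delta > 0 requires a non-empty effect_map")
    for roi, idxs in effect_map.items():
        idxs = np.asarray(idxs)
        if idxs.size and (idxs.min() < 0 or idxs.max() >= m):
            raise ValueError(f"effect_map for ROI {roi} has edge indices outside [0, {m})")

    idh_counts = idh_counts or _proportional_counts(n_patients, (25, 23))
    grade_counts = grade_counts or _proportional_counts(n_patients, (32, 16))
    if sum(idh_counts) != n_patients or sum(grade_counts) != n_patients:
        raise ValueError("idh_counts and grade_counts must sum to n_patients")

    if lesion_center_choices is None:
        lesion_center_choices = core_network(atlas)
    if lesion_radius_range is None:
        r_hi = max(3, min(atlas.grid_shape) // 3)
        lesion_radius_range = (2, r_hi)

    ss = np.random.SeedSequence(effect.seed)
    rng = np.random.default_rng(ss)

    # latent structure shared by the whole cohort
    mu_e = rng.normal(0.25, 0.15, size=m)
    pair_coupling = rng.uniform(*pair_coupling_range, size=n)  # control homotopic FC means
    interhemi_mu = np.full((n, n), 0.15)
    interhemi_mu[np.arange(n), np.arange(n)] = pair_coupling

    n_total = n_patients + n_controls
    intercepts = rng.normal(0.0, subject_intercept_sd, size=n_total)
    edges = mu_e[None, :] + intercepts[:, None] + rng.normal(0.0, effect.noise_sd,
                                                            size=(n_total, m))
    interhemi = interhemi_mu[None] + rng.normal(0.0, effect.noise_sd, size=(n_total, n, n))

    # patient metadata: exact genotype/grade counts, shuffled jointly
    idh = np.array(["mutant"] * idh_counts[0] + ["wildtype"] * idh_counts[1])
    grade = np.array(["high"] * grade_counts[0] + ["low"] * grade_counts[1])
    rng.shuffle(idh)
    rng.shuffle(grade)

    roi_volumes = np.bincount(atlas.label_image.ravel(), minlength=2 * n + 1)

    masks: list[LesionMask] = []
    centers: list[int] = []
    subjects: list[SubjectRecord] = []
    for p in range(n_patients):
        center = int(rng.choice(np.asarray(lesion_center_choices)))
        radius = int(rng.integers(lesion_radius_range[0], lesion_radius_range[1] + 1))
        mask = generate_lesion_mask(atlas, center, radius,
                                    seed=int(rng.integers(2**31 - 1)))
        # lesion-present left ROIs at the presence threshold drive the shift
        hit = np.bincount(atlas.label_image[mask.voxels.astype(bool)].ravel(),
                          minlength=2 * n + 1)
        lesioned = [int(roi) for roi in atlas.left_ids
                    if hit[roi] / roi_volumes[roi] >= presence_threshold]
        shift = np.zeros(m)
        for roi in lesioned:
            scale = effect.delta
            if effect.homotopic_scaling:
                scale *= pair_coupling[roi - 1]
            if idh[p] == "mutant":
                scale *= effect.idh_delta_ratio
            shift[effect_map.get(roi, np.array([], dtype=int))] += scale
        edges[p] += shift
        masks.append(mask)
        centers.append(center)
        subjects.append(
            SubjectRecord(
                subject_id=f"P{p + 1:03d}",
                group="patient",
                age=float(np.clip(rng.normal(50.0, 16.7), 18, 90)),
                sex="M" if rng.random() < 31 / 48 else "F",
                idh=str(idh[p]),
                who_grade=str(grade[p]),
                lesion_volume=mask.volume,
                lesion_mask_ref=p,
            )
        )
    for c in range(n_controls):
        subjects.append(
            SubjectRecord(
                subject_id=f"C{c + 1:03d}",
                group="control",
                age=float(np.clip(rng.normal(49.0, 15.9), 18, 90)),
                sex="M" if rng.random() < 44 / 107 else "F",
            )
        )

    return SyntheticCohort(
        atlas=atlas,
        subjects=tuple(subjects),
        edges=edges,
        masks=tuple(masks),
        interhemispheric=interhemi,
        pair_coupling=pair_coupling,
        lesion_centers=tuple(centers),
    )
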