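"""Ground-truthed synthetic blastocyst stacks and developmental tables.

The stack generator emulates what the confocal imaging of a day-6
blastocyst looks like to the segmentation pipeline: 20–60 ellipsoidal
nuclei arranged on a spherical shell (trophectoderm-like geometry), a
~10–13% apoptotic subset that is shrunken (pycnotic) and brighter and
co-labelled in the TUNEL channel, optional deliberately touching
bright/dim nucleus pairs, anisotropic voxels (2 µm optical sections),
and Poisson + Gaussian noise on top of a uniform background. The
developmental-table generator draws replicate × treatment binomial
outcomes with a replicate random intercept on the logit scale and
configurable treatment odds ratios, plus per-blastocyst ordinal stage
and grade draws — the exact structure the statistics layer models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_stacks import LabelVolume, VoxelStack

TREATMENTS = ("control", "PFOS", "PFHxS")
STAGES = ("early", "blastocyst", "expanding", "hatching")
GRADES = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


class PlacementError(RuntimeError):
    """Nuclei could not be placed without excessive overlap."""


@dataclass
class StackSimParams:
    """Geometry, intensity and noise settings for one synthetic stack.

    Defaults mirror the study conditions: ~36 nuclei per blastocyst,
    ~12% apoptotic, 2 µm z-sections. Lateral voxel size and intensity
    levels are assumptions documented in the methods note.
    """

    n_nuclei: int = 36
    apoptotic_fraction: float = 0.12
    nucleus_radius_um: float = 4.0
    nucleus_radius_sd_um: float = 0.5
    pycnotic_shrink_factor: float = 0.65
    shell_radius_um: float | None = None  # default: density-scaled, see below
    touching_pair_count: int = 0
    dapi_peak: float = 150.0
    apoptotic_dapi_peak: float = 210.0
    tunel_peak: float = 190.0
    dim_peak_factor: float = 0.45  # TUNEL peak factor of a touching pair's dim member
    background: float = 8.0
    read_noise_sd: float = 2.0
    poisson_noise: bool = True
    blur_sigma_um: float = 0.8
    voxel_size: tuple[float, float, float] = (2.0, 0.5, 0.5)
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.apoptotic_fraction <= 1.0:
            raise ValueError("apoptotic_fraction must lie in [0, 1]")
        if self.shell_radius_um is None:
            # keep the nuclear surface density blastocyst-like (~20% packing)
            # as n_nuclei varies: R = r * sqrt(n / (4 * 0.2))
            self.shell_radius_um = self.nucleus_radius_um * float(
                np.sqrt(max(self.n_nuclei, 8) / 0.8)
            )
        if self.nucleus_radius_um <= 0 or self.shell_radius_um <= 0:
            raise ValueError("radii must be positive")
        if not 0.0 < self.pycnotic_shrink_factor <= 1.0:
            raise ValueError("pycnotic_shrink_factor must lie in (0, 1]")
        if self.touching_pair_count * 2 > self.n_nuclei:
            raise ValueError("not enough nuclei for the requested touching pairs")


@dataclass
class GroundTruth:
    """Truth channel for recovery tests: labels + per-nucleus attributes."""

    labels: LabelVolume
    apoptotic: np.ndarray  # bool, index = label (0 unused)
    centroids: np.ndarray  # (n, 3) voxel coordinates
    radii_um: np.ndarray
    peak_intensity: np.ndarray

    @property
    def n_nuclei(self) -> int:
        return len(self.centroids)

    @property
    def n_apoptotic(self) -> int:
        return int(self.apoptotic[1:].sum())


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _render_ellipsoid(
    canvas: np.ndarray, center_um: np.ndarray, semi_um: np.ndarray,
    rot: np.ndarray, value: float, voxel_size: np.ndarray,
) -> np.ndarray:
    """Paint a solid rotated ellipsoid; returns the boolean support."""
    extent = np.sqrt((rot**2 @ semi_um**2))
    lo = np.maximum(np.floor((center_um - extent) / voxel_size).astype(int), 0)
    hi = np.minimum(np.ceil((center_um + extent) / voxel_size).astype(int) + 1, canvas.shape)
    if np.any(lo >= hi):
        return np.zeros((0, 3), int)
    grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    u = (pts * voxel_size - center_um) @ rot
    inside = (u**2 / semi_um**2).sum(axis=1) <= 1.0
    coords = pts[inside]
    if len(coords):
        view = canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        box = inside.reshape(tuple(hi - lo))
        view[box] = np.maximum(view[box], value)
    return coords


def generate_stack(params: StackSimParams) -> tuple[VoxelStack, GroundTruth]:
    """Render one two-channel synthetic blastocyst stack with ground truth.

    Deterministic for a fixed ``params.seed``. Raises
    :class:`PlacementError` if the nuclei cannot be placed on the shell
    within the overlap limit after bounded retries.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_nuclei
    voxel_size = np.asarray(params.voxel_size, float)
    pad = 3.0 * (params.nucleus_radius_um + 3 * params.nucleus_radius_sd_um)
    half = params.shell_radius_um + pad
    shape = tuple(int(np.ceil(2 * half / v)) for v in voxel_size)
    center = np.array(shape) * voxel_size / 2.0

    # declared touching pairs occupy indices (0,1), (2,3), ...; when the
    # stack has apoptotic nuclei the pairs are apoptotic bright/dim TUNEL
    # pairs (the configuration the iterative POE exists for)
    n_apop = int(round(n * params.apoptotic_fraction))
    pair_members = list(range(2 * params.touching_pair_count))
    apop_idx = set(pair_members[:n_apop])
    if len(apop_idx) < n_apop:
        rest = [i for i in rng.permutation(n).tolist() if i not in pair_members]
        apop_idx |= set(rest[: n_apop - len(apop_idx)])
    dim_partner = {2 * p + 1 for p in range(params.touching_pair_count)}
    radii = np.clip(
        rng.normal(params.nucleus_radius_um, params.nucleus_radius_sd_um, size=n),
        1.5, None,
    )
    for i in range(n):
        if i in apop_idx:
            radii[i] *= params.pycnotic_shrink_factor

    positions = np.empty((n, 3))
    placed = 0
    for i in range(n):
        if i in dim_partner:
            # touch the bright partner placed just before: surface contact
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            positions[i] = positions[i - 1] + direction * (radii[i - 1] + radii[i])
            placed += 1
            continue
        ok = False
        for _ in range(5000):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = params.shell_radius_um + rng.normal(0.0, 0.06 * params.shell_radius_um)
            cand = center + u * r
            prev = positions[:placed]
            if placed == 0 or np.all(
                np.linalg.norm(prev - cand, axis=1) >= 0.9 * (radii[:placed] + radii[i])
            ):
                positions[i] = cand
                ok = True
                break
        if not ok:
            raise PlacementError(f"could not place nucleus {i} after bounded retries")
        placed += 1

    dapi = np.zeros(shape)
    tunel = np.zeros(shape)
    labels = np.zeros(shape, np.int32)
    centroids = np.empty((n, 3))
    peaks = np.empty(n)
    apop_flags = np.zeros(n + 1, bool)
    for i in range(n):
        rot = _random_rotation(rng)
        semi = radii[i] * rng.uniform(0.85, 1.15, size=3)
        peak = params.apoptotic_dapi_peak if i in apop_idx else params.dapi_peak
        coords = _render_ellipsoid(dapi, positions[i], semi, rot, peak, voxel_size)
        if len(coords) == 0:
            raise PlacementError(f"nucleus {i} rendered empty (outside the grid?)")
        free = labels[tuple(coords.T)] == 0
        labels[tuple(coords[free].T)] = i + 1
        if not (labels == i + 1).any():
            raise PlacementError(f"nucleus {i} fully overdrawn by earlier nuclei")
        if i in apop_idx:
            tunel_peak = params.tunel_peak
            if i in dim_partner:
                tunel_peak *= params.dim_peak_factor
            _render_ellipsoid(tunel, positions[i], semi, rot, tunel_peak, voxel_size)
            apop_flags[i + 1] = True
        centroids[i] = positions[i] / voxel_size
        peaks[i] = peak

    sigma = params.blur_sigma_um / voxel_size
    channels = []
    for raw in (dapi, tunel):
        img = ndimage.gaussian_filter(raw, sigma) + params.background
        if params.poisson_noise:
            img = rng.poisson(img).astype(float)
        if params.read_noise_sd > 0:
            img = img + rng.normal(0.0, params.read_noise_sd, size=img.shape)
        img = np.clip(np.round(img), 0, 2**params.bit_depth - 1)
        channels.append(img.astype(np.uint8 if params.bit_depth == 8 else np.uint16))

    stack = VoxelStack(
        data=np.stack(channels),
        channels=("DAPI", "TUNEL"),
        voxel_size=tuple(voxel_size),
        bit_depth=params.bit_depth,
    )
    truth = GroundTruth(
        labels=LabelVolume(labels, tuple(voxel_size)),
        apoptotic=apop_flags,
        centroids=centroids,
        radii_um=radii,
        peak_intensity=peaks,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# touching bright/dim fixture


def make_touching_fixture(
    bright_peak: float = 200.0,
    dim_peak: float = 80.0,
    background: float = 10.0,
    radius_um: float = 4.0,
    voxel_size: tuple[float, float, float] = (2.0, 0.5, 0.5),
    blur_sigma_um: float = 0.8,
    read_noise_sd: float = 2.0,
    poisson_noise: bool = True,
    seed: int = 0,
) -> tuple[VoxelStack, GroundTruth]:
    """A single-channel pair of touching spheres no global threshold separates.

    The bright and dim spheres are in surface contact; after blurring,
    every grey level either keeps them connected (T at or below the dim
    interior) or loses the dim object entirely (T above it). That this
    holds is *verified at generation* by an exhaustive sweep over all
    grey levels; if a separating level is found the spheres are pushed
    closer and re-verified, and the function raises if none of the
    retries succeeds. This is precisely the failure mode of global
    thresholding that motivates the iterative POE loop. Shot and read
    noise match the stack generator (and keep the per-object threshold
    optimum at the object boundary rather than deep in a flat interior).
    """
    if dim_peak >= bright_peak:
        raise ValueError("dim_peak must be strictly below bright_peak")
    if min(dim_peak, bright_peak) <= background:
        raise ValueError("both peaks must exceed the background")
    rng = np.random.default_rng(seed)
    voxel_size = np.asarray(voxel_size, float)
    r_bright, r_dim = radius_um, 0.85 * radius_um

    for squeeze in (1.0, 0.92, 0.84, 0.76):
        gap = squeeze * (r_bright + r_dim)
        half = r_bright + r_dim + gap / 2 + 6.0
        shape = tuple(int(np.ceil(2 * half / v)) for v in voxel_size)
        center = np.array(shape) * voxel_size / 2.0
        axis = np.array([0.0, 1.0, 0.0])
        jitter = rng.normal(0, 0.02, size=3)
        axis = (axis + jitter) / np.linalg.norm(axis + jitter)
        c_bright = center - axis * gap / 2
        c_dim = center + axis * gap / 2

        img = np.zeros(shape)
        labels = np.zeros(shape, np.int32)
        eye = np.eye(3)
        co_b = _render_ellipsoid(img, c_bright, np.full(3, r_bright), eye, bright_peak, voxel_size)
        co_d = _render_ellipsoid(img, c_dim, np.full(3, r_dim), eye, dim_peak, voxel_size)
        labels[tuple(co_b.T)] = 1
        free = labels[tuple(co_d.T)] == 0
        labels[tuple(co_d[free].T)] = 2
        img = ndimage.gaussian_filter(img, blur_sigma_um / voxel_size) + background
        if poisson_noise:
            img = rng.poisson(img).astype(float)
        if read_noise_sd > 0:
            img = img + rng.normal(0.0, read_noise_sd, size=img.shape)
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)

        if not _separating_threshold_exists(img, labels == 1, labels == 2):
            stack = VoxelStack(
                data=img[None], channels=("TUNEL",),
                voxel_size=tuple(voxel_size), bit_depth=8,
            )
            truth = GroundTruth(
                labels=LabelVolume(labels, tuple(voxel_size)),
                apoptotic=np.zeros(3, bool),
                centroids=np.stack([c_bright / voxel_size, c_dim / voxel_size]),
                radii_um=np.array([r_bright, r_dim]),
                peak_intensity=np.array([bright_peak, dim_peak]),
            )
            return stack, truth
    raise RuntimeError(
        "could not build a touching fixture without a separating global threshold"
    )


def _separating_threshold_exists(
    img: np.ndarray, bright_mask: np.ndarray, dim_mask: np.ndarray
) -> bool:
    """Exhaustive sweep: does any grey level expose the dim object on its own?

    A level T is separating when some component of ``{I >= T}`` covers a
    substantial part (>= 5%) of the dim object's support while touching
    none of the bright object's — i.e. a global threshold at T would
    segment the dim object separately after all.
    """
    struct = ndimage.generate_binary_structure(3, 1)
    min_voxels = max(10, int(0.05 * dim_mask.sum()))
    for t in np.unique(img)[1:]:
        lab, n = ndimage.label(img >= t, structure=struct)
        dim_labs, counts = np.unique(lab[dim_mask & (lab > 0)], return_counts=True)
        bright_labs = set(np.unique(lab[bright_mask & (lab > 0)]).tolist())
        for dl, cnt in zip(dim_labs, counts):
            if cnt >= min_voxels and dl not in bright_labs:
                return True
    return False


# ---------------------------------------------------------------------------
# developmental tables


@dataclass
class DevSimParams:
    """Replicate-level developmental outcome simulation settings.

    Defaults follow the study design: nine replicates of three groups of
    28–40 oocytes, baseline outcome probabilities at the control-group
    means (cleaved 0.38; cleaved beyond 2-cell 0.59 of cleaved;
    blastocyst 0.07 on day 5 and 0.15 on day 6), and a replicate random
    intercept on the logit scale.
    """

    n_replicates: int = 9
    oocytes_per_group: tuple[int, int] = (28, 40)
    baselines: Mapping[str, float] = field(
        default_factory=lambda: {
            "cleaved": 0.38,
            "cleaved_gt2": 0.59,
            "blastocyst_d5": 0.07,
            "blastocyst_d6": 0.15,
        }
    )
    odds_ratios: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    replicate_sd: float = 0.3
    stage_probs: Sequence[float] = (0.25, 0.35, 0.30, 0.10)
    grade_probs: Sequence[float] = (0.30, 0.20, 0.20, 0.12, 0.08, 0.05, 0.05)
    stage_or: Mapping[str, float] = field(default_factory=dict)
    grade_or: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in self.baselines.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"baseline {name} must lie in (0, 1)")
        if self.oocytes_per_group[0] < 1:
            raise ValueError("need at least one oocyte per group")


def _ilogit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _ordinal_draw(rng, n, probs, beta, u):
    """Cumulative-logit draw of n ordinal outcomes shifted by beta + u."""
    probs = np.asarray(probs, float)
    kappa = np.log(np.cumsum(probs)[:-1] / (1 - np.cumsum(probs)[:-1]))
    cum = _ilogit(kappa[None, :] - (beta + u))
    r = rng.uniform(size=(n, 1))
    return (r > cum).sum(axis=1)


def generate_dev_table(params: DevSimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one study: group-level counts and per-blastocyst ordinals.

    Returns ``(groups, blastocysts)``. ``groups`` has one row per
    replicate × treatment with columns replicate, treatment, n_oocytes
    and the four endpoint success counts (``cleaved_gt2`` is drawn from
    the cleaved embryos, matching its denominator in the analysis).
    ``blastocysts`` has one row per day-6 blastocyst with its ordinal
    stage and grade.
    """
    rng = np.random.default_rng(params.seed)
    endpoints = list(params.baselines)
    u = {
        ep: rng.normal(0.0, params.replicate_sd, size=params.n_replicates)
        for ep in endpoints
    }
    u_stage = rng.normal(0.0, params.replicate_sd, size=params.n_replicates)
    u_grade = rng.normal(0.0, params.replicate_sd, size=params.n_replicates)

    group_rows, blast_rows = [], []
    for rep in range(1, params.n_replicates + 1):
        for trt in TREATMENTS:
            n = int(rng.integers(params.oocytes_per_group[0], params.oocytes_per_group[1] + 1))
            row = {"replicate": rep, "treatment": trt, "n_oocytes": n}
            for ep in endpoints:
                oratio = params.odds_ratios.get(ep, {}).get(trt, 1.0)
                eta = (
                    np.log(params.baselines[ep] / (1 - params.baselines[ep]))
                    + np.log(oratio)
                    + u[ep][rep - 1]
                )
                denom = row["cleaved"] if ep == "cleaved_gt2" else n
                row[ep] = int(rng.binomial(denom, _ilogit(eta))) if denom > 0 else 0
            group_rows.append(row)

            n_blast = row["blastocyst_d6"]
            if n_blast > 0:
                stages = _ordinal_draw(
                    rng, n_blast, params.stage_probs,
                    np.log(params.stage_or.get(trt, 1.0)), u_stage[rep - 1],
                )
                grades = _ordinal_draw(
                    rng, n_blast, params.grade_probs,
                    np.log(params.grade_or.get(trt, 1.0)), u_grade[rep - 1],
                )
                for s, g in zip(stages, grades):
                    blast_rows.append(
                        {"replicate": rep, "treatment": trt,
                         "stage": STAGES[s], "grade": GRADES[g]}
                    )
    groups = pd.DataFrame(group_rows)
    blasts = pd.DataFrame(blast_rows, columns=["replicate", "treatment", "stage", "grade"])
    groups.attrs["replicate_effects"] = {**u, "stage": u_stage, "grade": u_grade}
    return groups, blasts


# ---------------------------------------------------------------------------
# per-embryo metrics tables (for exercising the count/apoptosis models)


@dataclass
class MetricsSimParams:
    """Per-embryo nucleus-count and apoptosis simulation settings.

    Counts are log-normal around the study's control mean (~36 nuclei);
    apoptotic counts are binomial with a proportion that may depend
    linearly on nucleus count (the size–apoptosis association) and on
    treatment.
    """

    n_replicates: int = 9
    embryos_per_group: int = 5
    mean_nuclei: float = 35.8
    log_count_sd: float = 0.45
    count_effect: Mapping[str, float] = field(default_factory=dict)  # multiplicative
    base_prop: float = 0.104
    prop_slope_per_nucleus: float = 0.0
    prop_effect: Mapping[str, float] = field(default_factory=dict)  # additive
    replicate_sd_log_count: float = 0.15
    replicate_sd_prop: float = 0.02
    seed: int = 0


def generate_metrics_table(params: MetricsSimParams) -> pd.DataFrame:
    """Simulate an :class:`~tunel3d.apoptosis.EmbryoMetrics`-shaped table."""
    rng = np.random.default_rng(params.seed)
    u_count = rng.normal(0.0, params.replicate_sd_log_count, size=params.n_replicates)
    u_prop = rng.normal(0.0, params.replicate_sd_prop, size=params.n_replicates)
    rows = []
    eid = 0
    for rep in range(1, params.n_replicates + 1):
        for trt in TREATMENTS:
            for _ in range(params.embryos_per_group):
                eid += 1
                mu = (
                    np.log(params.mean_nuclei)
                    + np.log(params.count_effect.get(trt, 1.0))
                    + u_count[rep - 1]
                )
                n_nuc = max(4, int(np.round(np.exp(rng.normal(mu, params.log_count_sd)))))
                p = (
                    params.base_prop
                    + params.prop_slope_per_nucleus * (n_nuc - params.mean_nuclei)
                    + params.prop_effect.get(trt, 0.0)
                    + u_prop[rep - 1]
                )
                p = float(np.clip(p, 1e-4, 1 - 1e-4))
                n_apop = int(rng.binomial(n_nuc, p))
                rows.append(
                    {"embryo_id": f"E{eid:04d}", "treatment": trt, "replicate": rep,
                     "n_nuclei": n_nuc, "n_apoptotic": n_apop,
                     "prop_apoptotic": n_apop / n_nuc,
                     "excluded": False, "exclusion_reason": ""}
                )
    return pd.DataFrame(rows)
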