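"""Per-object ellipsoid-fit (POE) segmentation in 3D.

The TUNEL channel of a blastocyst stack contains a handful of bright,
roughly ellipsoidal apoptotic nuclei on a dark background, sometimes in
contact with brighter neighbours. A single global threshold cannot
separate a dim nucleus touching a bright one: every level either merges
the pair or loses the dim object. POE instead chooses a *local*
threshold per object — the level at which the thresholded component
looks most like a solid ellipsoid, subject to minimum/maximum diameter
criteria — and an iterative variant rescues dim objects by blacking out
already-segmented voxels and re-running the search.

The search space of candidate objects is the max-tree (component tree of
upper level sets): each node is a connected component of ``{I >= T}``
for the levels T in a contiguous range, so optimising a per-object
threshold is a selection problem on root-to-leaf branches of the tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import watershed

from .io_stacks import LabelVolume, SegConfig

logger = logging.getLogger("tunel3d")

_NEG = -np.inf


@dataclass
class EllipsoidFit:
    """Second-moment ellipsoid summary of a binary 3D region.

    ``fit_score`` is the Jaccard overlap between the region and the
    digitized solid ellipsoid with the same centroid and second central
    moments; 1 means a perfect (digitized) ellipsoid. Equivalent axis
    diameters are ``d_i = 4 * sqrt(lambda_i)`` from the moment
    eigenvalues, sorted descending, in µm.
    """

    centroid: np.ndarray  # (z, y, x) voxel coordinates
    moments: np.ndarray  # 3x3 second central moment matrix, µm²
    fit_score: float
    diameters_um: np.ndarray  # descending

    @property
    def max_diameter_um(self) -> float:
        return float(self.diameters_um[0])


@dataclass
class PoeResult:
    """Objects, eroded seeds and per-object records from a POE run."""

    objects: LabelVolume
    seeds: LabelVolume
    records: pd.DataFrame  # label, threshold, fit_score, volume_um3, d*_um, iteration_found
    iterations_used: int = 1
    warnings: list = field(default_factory=list)

    @property
    def n_objects(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# ellipsoid fit


def _moment_eigen(coords: np.ndarray, voxel_size) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Centroid (phys), covariance (phys), eigenvalues asc, eigenvectors."""
    phys = coords * np.asarray(voxel_size, float)
    centroid = phys.mean(axis=0)
    centred = phys - centroid
    cov = centred.T @ centred / len(phys)
    lam, vec = np.linalg.eigh(cov)
    return centroid, cov, lam, vec


def _digitized_ellipsoid_score(
    coords: np.ndarray, voxel_size, shape
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Jaccard of the region against its equal-moment digitized ellipsoid.

    For a solid uniform ellipsoid with semi-axes a_i the covariance
    eigenvalues are a_i²/5, so the matched ellipsoid has semi-axes
    sqrt(5·λ_i). Degenerate eigenvalues are floored at the variance of a
    uniform distribution over one voxel so that flat regions still
    digitize to a non-empty ellipsoid.
    """
    voxel_size = np.asarray(voxel_size, float)
    if len(coords) == 1:  # single voxel: perfect by convention
        centroid, cov, lam, _ = _moment_eigen(coords, voxel_size)
        return 1.0, centroid, cov, lam
    centroid, cov, lam, vec = _moment_eigen(coords, voxel_size)
    floor = (voxel_size.min() ** 2) / 12.0
    lam_f = np.maximum(lam, floor)
    semi = np.sqrt(5.0 * lam_f)

    # bounding box of the ellipsoid in voxel indices, clipped to the grid
    extent = np.sqrt((vec**2 @ (semi**2)))  # per-axis physical half-extent
    lo = np.maximum(np.floor((centroid - extent) / voxel_size).astype(int), 0)
    hi = np.minimum(
        np.ceil((centroid + extent) / voxel_size).astype(int) + 1, np.asarray(shape)
    )
    lo = np.minimum(lo, coords.min(axis=0))
    hi = np.maximum(hi, coords.max(axis=0) + 1)

    grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1) * voxel_size - centroid
    u = pts @ vec
    inside = (u**2 / (5.0 * lam_f)).sum(axis=1) <= 1.0

    box_shape = tuple(hi - lo)
    ell = inside.reshape(box_shape)
    reg = np.zeros(box_shape, bool)
    reg[tuple((coords - lo).T)] = True
    inter = np.logical_and(reg, ell).sum()
    union = np.logical_or(reg, ell).sum()
    score = float(inter) / float(union) if union else 0.0
    return score, centroid, cov, lam


def ellipsoid_fit_score(region: np.ndarray, voxel_size=(2.0, 0.31, 0.31)) -> EllipsoidFit:
    """Score how ellipsoid-like a binary 3D region is.

    Raises ``ValueError`` on an empty region. A single-voxel region
    scores 1 by convention.
    """
    region = np.asarray(region).astype(bool)
    if region.ndim != 3:
        raise ValueError("region must be 3D")
    coords = np.argwhere(region)
    if len(coords) == 0:
        raise ValueError("empty region")
    score, centroid, cov, lam = _digitized_ellipsoid_score(coords, voxel_size, region.shape)
    diameters = 4.0 * np.sqrt(np.maximum(lam, 0.0))[::-1]
    return EllipsoidFit(
        centroid=centroid / np.asarray(voxel_size, float),
        moments=cov,
        fit_score=score,
        diameters_um=diameters,
    )


# ---------------------------------------------------------------------------
# component tree

def _neighbor_offsets(connectivity: int) -> np.ndarray:
    """(m, 3) integer offsets of the 6- or 26-neighbourhood."""
    if connectivity == 6:
        return np.array(
            [[-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0], [0, 0, -1], [0, 0, 1]],
            np.int64,
        )
    offs = [
        [dz, dy, dx]
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    return np.array(offs, np.int64)


def _sym3_eigvalsh(cov: np.ndarray) -> np.ndarray:
    """Eigenvalues (ascending) of a batch of symmetric 3x3 matrices.

    Closed-form trigonometric solution; avoids a LAPACK call per node
    when screening every component-tree node for the diameter criteria.
    """
    a = cov
    q = (a[:, 0, 0] + a[:, 1, 1] + a[:, 2, 2]) / 3.0
    p1 = a[:, 0, 1] ** 2 + a[:, 0, 2] ** 2 + a[:, 1, 2] ** 2
    p2 = (
        (a[:, 0, 0] - q) ** 2 + (a[:, 1, 1] - q) ** 2 + (a[:, 2, 2] - q) ** 2 + 2.0 * p1
    )
    p = np.sqrt(np.maximum(p2 / 6.0, 0.0))
    safe = p > 1e-30
    b = (a - q[:, None, None] * np.eye(3)) / np.where(safe, p, 1.0)[:, None, None]
    detb = (
        b[:, 0, 0] * (b[:, 1, 1] * b[:, 2, 2] - b[:, 1, 2] ** 2)
        - b[:, 0, 1] * (b[:, 0, 1] * b[:, 2, 2] - b[:, 1, 2] * b[:, 0, 2])
        + b[:, 0, 2] * (b[:, 0, 1] * b[:, 1, 2] - b[:, 1, 1] * b[:, 0, 2])
    )
    phi = np.arccos(np.clip(detb / 2.0, -1.0, 1.0)) / 3.0
    e1 = q + 2.0 * p * np.cos(phi)
    e3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e2 = 3.0 * q - e1 - e3
    lam = np.stack([e3, e2, e1], axis=1)
    lam[~safe] = q[~safe, None]
    return lam


class ComponentTree:
    """Max-tree of an image with per-node supports, sizes and moments.

    Nodes are canonical components. ``pre_order`` lists node indices
    with parents before children, and (when built with
    ``need_moments=True``) each node's voxel support is the contiguous
    slice ``euler_pixels[start:end]`` (an Euler-tour layout), so subtree
    sums are prefix-sum differences.
    """

    def __init__(
        self,
        image: np.ndarray,
        connectivity: int = 6,
        voxel_size=(1.0, 1.0, 1.0),
        need_moments: bool = True,
    ):
        from ._tree_accel import euler_tour, max_tree_parents, push_up

        image = np.asarray(image)
        if image.ndim != 3:
            raise ValueError("ComponentTree expects a 3D image")
        self.shape = image.shape
        self.voxel_size = np.asarray(voxel_size, float)
        vals = image.ravel()
        n = vals.size

        sort_asc = np.argsort(vals, kind="stable").astype(np.int64)
        par = max_tree_parents(
            vals.astype(np.int64), sort_asc, *image.shape, _neighbor_offsets(connectivity)
        )
        trav = sort_asc
        idx = np.arange(n)
        root = int(trav[0])
        is_canon = (idx == root) | (vals[par] != vals)
        canon_of = np.where(is_canon, idx, par)

        canon_pixels = idx[is_canon]  # ascending flat index = node id order
        k = len(canon_pixels)
        node_index_of = np.full(n, -1, np.int64)
        node_index_of[canon_pixels] = np.arange(k)
        node_parent = node_index_of[par[canon_pixels]]
        root_node = int(node_index_of[root])

        # topological node order from the max-tree traverser
        canon_trav = trav[is_canon[trav]]
        topo = node_index_of[canon_trav]

        sizes = np.bincount(node_index_of[canon_of], minlength=k).astype(np.int64)
        self._proper_sizes = sizes.copy()
        push_up(topo, node_parent, sizes)

        self.vals = vals
        self.root_node = root_node
        self.n_nodes = k
        self.canon_pixels = canon_pixels
        self.node_parent = node_parent
        self.level = np.asarray(vals[canon_pixels])
        self._sizes = sizes
        self._topo = topo
        self._has_moments = False

        if need_moments:
            # children adjacency grouped by parent (children ascend by node id)
            order = np.argsort(node_parent, kind="stable")
            order = order[order != root_node]
            child_off = np.zeros(k + 1, np.int64)
            np.add.at(child_off, node_parent[order] + 1, 1)
            child_off = np.cumsum(child_off)

            pix_sort = np.argsort(canon_of, kind="stable")
            sorted_canon = canon_of[pix_sort]
            grp_start = np.searchsorted(sorted_canon, canon_pixels, side="left")
            grp_end = np.searchsorted(sorted_canon, canon_pixels, side="right")

            euler, start, end, pre_order = euler_tour(
                node_parent, order, child_off, pix_sort, grp_start, grp_end, root_node
            )
            self.euler_pixels = euler
            self.start = start
            self.end = end
            self.pre_order = pre_order

            coords = np.stack(np.unravel_index(euler, self.shape), axis=1).astype(np.float64)
            coords *= self.voxel_size
            prods = np.empty((n, 6))
            prods[:, 0] = coords[:, 0] ** 2
            prods[:, 1] = coords[:, 1] ** 2
            prods[:, 2] = coords[:, 2] ** 2
            prods[:, 3] = coords[:, 0] * coords[:, 1]
            prods[:, 4] = coords[:, 0] * coords[:, 2]
            prods[:, 5] = coords[:, 1] * coords[:, 2]
            self._s1 = np.vstack([np.zeros(3), np.cumsum(coords, axis=0)])
            self._s2 = np.vstack([np.zeros(6), np.cumsum(prods, axis=0)])
            self._has_moments = True

    def node_coords(self, node: int) -> np.ndarray:
        """Voxel (z, y, x) indices of the node's full component support."""
        flat = self.euler_pixels[self.start[node] : self.end[node]]
        return np.stack(np.unravel_index(flat, self.shape), axis=1)

    def node_sizes(self) -> np.ndarray:
        return self._sizes

    def node_covariances(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-node (count, 3x3 covariance in µm²), vectorised."""
        if not self._has_moments:
            raise RuntimeError("tree was built with need_moments=False")
        cnt = (self.end - self.start).astype(np.float64)
        s1 = self._s1[self.end] - self._s1[self.start]
        s2 = self._s2[self.end] - self._s2[self.start]
        mean = s1 / cnt[:, None]
        cov = np.empty((self.n_nodes, 3, 3))
        cov[:, 0, 0] = s2[:, 0] / cnt - mean[:, 0] ** 2
        cov[:, 1, 1] = s2[:, 1] / cnt - mean[:, 1] ** 2
        cov[:, 2, 2] = s2[:, 2] / cnt - mean[:, 2] ** 2
        cov[:, 0, 1] = cov[:, 1, 0] = s2[:, 3] / cnt - mean[:, 0] * mean[:, 1]
        cov[:, 0, 2] = cov[:, 2, 0] = s2[:, 4] / cnt - mean[:, 0] * mean[:, 2]
        cov[:, 1, 2] = cov[:, 2, 1] = s2[:, 5] / cnt - mean[:, 1] * mean[:, 2]
        return cnt, cov


# ---------------------------------------------------------------------------
# POE segmentation


def poe_segment(
    image: np.ndarray,
    config: SegConfig | None = None,
    voxel_size=None,
) -> PoeResult:
    """Segment ellipsoidal objects with per-object optimal thresholds.

    Every max-tree node is a candidate object at its own threshold.
    A node *conforms* when its smallest equivalent axis diameter is at
    least ``min_diameter_um``, its largest at most ``max_diameter_um``
    (so thin noise clumps cannot qualify through one long axis), and its
    fit score reaches ``min_fit_score``; candidate thresholds lie
    strictly above the global minimum (the background level is never an
    object threshold). Selection is top-down: descending from the root,
    a candidate is selected when its score is within
    ``fit_score_tolerance`` of the best candidate score in its subtree —
    i.e. the *largest* object whose fit is essentially as good as any
    nested refinement — and selection blocks all its descendants, so
    selected nodes are pairwise disjoint.
    """
    config = config or SegConfig()
    voxel_size = tuple(voxel_size if voxel_size is not None else config.voxel_size)
    image = np.asarray(image)
    labels = np.zeros(image.shape, np.int32)
    empty = PoeResult(
        objects=LabelVolume(labels, voxel_size),
        seeds=LabelVolume(labels.copy(), voxel_size),
        records=_empty_records(),
    )
    if image.size == 0 or image.max() == image.min():
        return empty

    tree = ComponentTree(image, config.connectivity, voxel_size)
    cnt, cov = tree.node_covariances()
    lam = _sym3_eigvalsh(cov)  # ascending per node
    d_min = 4.0 * np.sqrt(np.maximum(lam[:, 0], 0.0))
    d_max = 4.0 * np.sqrt(np.maximum(lam[:, 2], 0.0))
    vmin = int(image.min())
    eps = 1e-6  # discrete voxel sets routinely land exactly on a bound
    conforming = (
        (tree.level > vmin)
        & (d_min >= config.min_diameter_um - eps)
        & (d_max <= config.max_diameter_um + eps)
    )

    score = np.full(tree.n_nodes, _NEG)
    for node in np.flatnonzero(conforming):
        coords = tree.node_coords(node)
        s, *_ = _digitized_ellipsoid_score(coords, voxel_size, image.shape)
        score[node] = s
    candidate = conforming & (score >= config.min_fit_score)
    if not candidate.any():
        return empty

    # top-down selection: pick the largest candidate whose score is
    # within tolerance of the best candidate score in its subtree
    from ._tree_accel import select_top_down, subtree_max

    sub_max = np.full(tree.n_nodes, _NEG)
    subtree_max(tree.pre_order, tree.node_parent, score, candidate, sub_max)
    selected = np.zeros(tree.n_nodes, np.bool_)
    select_top_down(
        tree.pre_order, tree.node_parent, score, candidate, sub_max,
        config.fit_score_tolerance, tree.root_node, selected,
    )

    chosen = np.flatnonzero(selected)
    chosen = chosen[np.argsort(tree.start[chosen], kind="stable")]
    voxvol = float(np.prod(voxel_size))
    rows = []
    for lab, node in enumerate(chosen, start=1):
        coords = tree.node_coords(node)
        labels[tuple(coords.T)] = lab
        dd = 4.0 * np.sqrt(np.maximum(lam[node][::-1], 0.0))
        rows.append(
            {
                "label": lab,
                "threshold": int(tree.level[node]),
                "fit_score": float(score[node]),
                "volume_um3": cnt[node] * voxvol,
                "d1_um": dd[0],
                "d2_um": dd[1],
                "d3_um": dd[2],
                "iteration_found": 1,
            }
        )
    records = pd.DataFrame(rows) if rows else _empty_records()
    objects = LabelVolume(labels, voxel_size)
    seeds = _erode_objects(objects, image, config.erosion_voxels, config.connectivity)
    return PoeResult(objects=objects, seeds=seeds, records=records)


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "label",
            "threshold",
            "fit_score",
            "volume_um3",
            "d1_um",
            "d2_um",
            "d3_um",
            "iteration_found",
        ]
    )


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def _erode_objects(
    objects: LabelVolume, image: np.ndarray, erosion_voxels: int, connectivity: int = 6
) -> LabelVolume:
    """Erode each object independently; a vanished object keeps its
    brightest voxel so it cannot drop out of the watershed."""
    labels = objects.labels
    seeds = np.zeros_like(labels, dtype=np.int32)
    if labels.max() == 0:
        return LabelVolume(seeds, objects.voxel_size)
    struct = _structure(connectivity)
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        mask = labels[sl] == lab
        if erosion_voxels > 0:
            eroded = ndimage.binary_erosion(
                mask, structure=struct, iterations=erosion_voxels
            )
        else:
            eroded = mask
        if not eroded.any():
            img = np.where(mask, image[sl], -1)
            flat = int(np.argmax(img))
            eroded = np.zeros_like(mask)
            eroded[np.unravel_index(flat, mask.shape)] = True
        seeds[sl][eroded] = lab
    return LabelVolume(seeds, objects.voxel_size)


def iterative_poe_segment(
    image: np.ndarray,
    config: SegConfig | None = None,
    voxel_size=None,
) -> PoeResult:
    """POE with iterative black-out of already-segmented objects.

    Each round runs :func:`poe_segment`, keeps the eroded objects as
    seeds, blacks the segmented voxels out of a working copy and
    re-segments, merging new objects and seeds under fresh labels, until
    a round finds nothing (or ``max_iterations`` is reached, which is
    recorded as a warning). Objects found in earlier rounds are never
    modified, so the final result is a superset of every round's output.
    """
    config = config or SegConfig()
    voxel_size = tuple(voxel_size if voxel_size is not None else config.voxel_size)
    work = np.asarray(image).copy()
    labels = np.zeros(work.shape, np.int32)
    seeds = np.zeros(work.shape, np.int32)
    frames: list[pd.DataFrame] = []
    warnings: list[str] = []
    iterations = 0
    while iterations < config.max_iterations:
        iterations += 1
        res = poe_segment(work, config, voxel_size)
        if res.n_objects == 0:
            break
        offset = int(labels.max())
        new = res.objects.labels
        labels[new > 0] = new[new > 0] + offset
        new_seeds = res.seeds.labels
        seeds[new_seeds > 0] = new_seeds[new_seeds > 0] + offset
        rec = res.records.copy()
        rec["label"] += offset
        rec["iteration_found"] = iterations
        frames.append(rec)
        work[new > 0] = 0
    else:
        msg = f"max_iterations={config.max_iterations} reached with objects still found"
        warnings.append(msg)
        logger.warning(msg)
    records = pd.concat(frames, ignore_index=True) if frames else _empty_records()
    return PoeResult(
        objects=LabelVolume(labels, voxel_size),
        seeds=LabelVolume(seeds, voxel_size),
        records=records,
        iterations_used=iterations,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# seeded watershed split


def watershed_split(
    mask: np.ndarray,
    seeds: LabelVolume | np.ndarray,
    voxel_size=(2.0, 0.31, 0.31),
    connectivity: int = 6,
) -> LabelVolume:
    """Partition a binary mask among seed labels by distance-transform flooding.

    The flooding priority is the negated Euclidean distance transform of
    the mask, physically scaled. Seed voxels outside the mask are
    discarded with a warning; if no seed intersects a non-empty mask the
    whole mask is returned as one fresh object. Mask components that
    contain no seed also receive fresh labels (with a warning) so that
    the output always partitions the mask exactly.
    """
    seed_arr = seeds.labels if isinstance(seeds, LabelVolume) else np.asarray(seeds)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != seed_arr.shape:
        raise ValueError("mask and seeds must share a shape")
    inside = np.where(mask, seed_arr, 0)
    dropped = set(np.unique(seed_arr[seed_arr > 0])) - set(np.unique(inside[inside > 0]))
    if dropped:
        logger.warning("watershed_split: %d seed(s) outside mask discarded", len(dropped))
    if not mask.any():
        return LabelVolume(np.zeros(mask.shape, np.int32), voxel_size)
    if not inside.any():
        logger.warning("watershed_split: no seeds intersect mask; returning one object")
        return LabelVolume(mask.astype(np.int32), voxel_size)

    edt = ndimage.distance_transform_edt(mask, sampling=voxel_size)
    out = watershed(
        -edt, markers=inside, mask=mask, connectivity=_structure(connectivity)
    )
    unassigned = mask & (out == 0)
    if unassigned.any():
        extra, n_extra = ndimage.label(unassigned, structure=_structure(connectivity))
        out = out + np.where(extra > 0, extra + out.max(), 0)
        logger.warning(
            "watershed_split: %d seedless mask component(s) given fresh labels", n_extra
        )
    from .io_stacks import relabel_contiguous

    return LabelVolume(relabel_contiguous(out), voxel_size)
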