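"""Brute-force reference implementations for validating the segmentation core.

These recompute the per-object-threshold selection and the SIP sweep by
their definitions — threshold the image at every grey level, enumerate
connected components with ``scipy.ndimage.label``, and compare
candidates by explicit subset tests — with no component tree and no
incremental counting. They are exponential-ish in image size and meant
for small images only (tests and the ``validate`` CLI subcommand).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .io_stacks import SegConfig


def _oracle_score(coords: np.ndarray, shape, voxel_size) -> float:
    """Jaccard with the equal-moment digitized ellipsoid, full-grid version."""
    voxel_size = np.asarray(voxel_size, float)
    if len(coords) == 1:
        return 1.0
    phys = coords * voxel_size
    mu = phys.mean(axis=0)
    cov = np.cov(phys.T, bias=True)
    lam, vec = np.linalg.eigh(cov)
    lam = np.maximum(lam, (voxel_size.min() ** 2) / 12.0)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1) * voxel_size - mu
    inside = ((pts @ vec) ** 2 / (5.0 * lam)).sum(axis=1) <= 1.0
    ell = inside.reshape(shape)
    reg = np.zeros(shape, bool)
    reg[tuple(coords.T)] = True
    return float((reg & ell).sum()) / float((reg | ell).sum())


def _oracle_diameters(coords: np.ndarray, voxel_size) -> tuple[float, float]:
    """(smallest, largest) equivalent axis diameter of a voxel set."""
    voxel_size = np.asarray(voxel_size, float)
    phys = coords * voxel_size
    cov = np.cov(phys.T, bias=True) if len(coords) > 1 else np.zeros((3, 3))
    lam = np.clip(np.linalg.eigvalsh(np.atleast_2d(cov)), 0.0, None)
    return float(4.0 * np.sqrt(lam.min())), float(4.0 * np.sqrt(lam.max()))


def poe_sweep_oracle(
    image: np.ndarray, config: SegConfig, voxel_size=None
) -> set[tuple[frozenset, int]]:
    """Exhaustive-sweep POE: the selected (support, threshold) pairs.

    Candidates are connected components of ``{I >= T}`` for every grey
    level T above the global minimum whose smallest equivalent axis
    diameter reaches ``min_diameter_um``, whose largest stays within
    ``max_diameter_um`` and whose ellipsoid-fit score reaches the floor;
    identical supports arising at several levels keep the highest
    level. Selection is top-down by decreasing support size: a candidate
    is selected when its score is within ``fit_score_tolerance`` of the
    best score among candidates nested inside it (itself included) and
    it is not contained in an already-selected candidate.
    """
    voxel_size = tuple(voxel_size if voxel_size is not None else config.voxel_size)
    image = np.asarray(image)
    struct = ndimage.generate_binary_structure(3, 1 if config.connectivity == 6 else 3)
    candidates: dict[frozenset, tuple[int, float]] = {}
    for t in np.unique(image)[1:]:
        lab, n = ndimage.label(image >= t, structure=struct)
        for k in range(1, n + 1):
            coords = np.argwhere(lab == k)
            d_lo, d_hi = _oracle_diameters(coords, voxel_size)
            eps = 1e-6  # same boundary slack as the tree implementation
            if d_lo < config.min_diameter_um - eps or d_hi > config.max_diameter_um + eps:
                continue
            score = _oracle_score(coords, image.shape, voxel_size)
            if score < config.min_fit_score:
                continue
            support = frozenset(map(tuple, coords))
            prev = candidates.get(support)
            if prev is None or t > prev[0]:
                candidates[support] = (int(t), score)

    items = sorted(candidates.items(), key=lambda kv: (-len(kv[0]), kv[1][0]))
    selected: list[tuple[frozenset, int]] = []
    for sup, (t, score) in items:
        if any(sup <= chosen for chosen, _ in selected):
            continue
        nested_best = max(s2 for other, (t2, s2) in candidates.items() if other <= sup)
        if score >= nested_best - config.fit_score_tolerance:
            selected.append((sup, t))
    return {(sup, t) for sup, t in selected}


def sip_sweep_oracle(
    image: np.ndarray,
    size_interval: tuple[float, float],
    config: SegConfig,
    voxel_size=None,
) -> tuple[float, int, float]:
    """Naive SizeIntervalPrecision sweep: (threshold, n_conforming, precision)."""
    from .nuclei_seg import NoConformingThreshold

    voxel_size = tuple(voxel_size if voxel_size is not None else config.voxel_size)
    voxvol = float(np.prod(voxel_size))
    vmin, vmax = size_interval
    struct = ndimage.generate_binary_structure(3, 1 if config.connectivity == 6 else 3)
    if len(np.unique(image)) < 2:
        raise NoConformingThreshold("image is flat (oracle)")
    best = None
    for t in np.unique(image):
        fg = image >= t
        lab, n = ndimage.label(fg, structure=struct)
        sizes = np.bincount(lab.ravel())[1:]
        conf = (sizes * voxvol >= vmin) & (sizes * voxvol <= vmax)
        n_conf = int(conf.sum())
        total = int(fg.sum())
        precision = float(sizes[conf].sum()) / total if total else 0.0
        if config.sip_objective == "precision-first":
            key = (precision, n_conf, -float(t))
        else:
            key = (n_conf, precision, -float(t))
        if best is None or key > best[0]:
            best = (key, (float(t), n_conf, precision))
    if best is None or best[1][1] == 0:
        raise NoConformingThreshold("no size-conforming threshold (oracle)")
    return best[1]
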