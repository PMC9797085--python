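"""DAPI nucleus segmentation: size-interval global thresholding + watershed.

All nuclei in a blastocyst stack are similar in size, so a good global
threshold is the one that maximises the number of connected components
whose volume falls inside a nucleus-sized interval — the
SizeIntervalPrecision (SIP) criterion. Touching nuclei in the resulting
mask are then split with a seeded watershed, seeded at regional maxima
of the mask's Euclidean distance map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import h_maxima, local_maxima

from .io_stacks import LabelVolume, SegConfig, relabel_contiguous
from .poe3d import ComponentTree, _structure, watershed_split

logger = logging.getLogger("tunel3d")


class NoConformingThreshold(ValueError):
    """No grey level produced any component inside the size interval."""


@dataclass
class SipResult:
    """Winning threshold of a SizeIntervalPrecision sweep.

    ``precision`` is the fraction of foreground voxels (at the winning
    threshold) that belong to size-conforming components.
    """

    threshold: float
    n_conforming: int
    precision: float
    mask: np.ndarray


def _bin_levels(image: np.ndarray, max_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-bin an image to <= max_levels candidate levels.

    Each bin is represented by its lowest original grey level, so
    thresholding the binned image at a representative is identical to
    thresholding the original image there; the approximation is only
    that intermediate levels are no longer candidates. Exact for <=
    ``max_levels`` distinct values (e.g. any 8/10-bit image).
    """
    distinct, counts = np.unique(image, return_counts=True)
    if len(distinct) <= max_levels:
        return image, distinct
    cum = np.cumsum(counts) / counts.sum()
    edges = np.searchsorted(cum, np.linspace(0, 1, max_levels + 1)[1:-1], side="left")
    group = np.zeros(len(distinct), np.int64)
    starts = np.unique(np.clip(edges + 1, 1, len(distinct) - 1))
    group[starts] = 1
    group = np.cumsum(group)
    reps = np.array([distinct[group == g].min() for g in range(group[-1] + 1)])
    lut = reps[group]
    binned = lut[np.searchsorted(distinct, image.ravel())].reshape(image.shape)
    return binned, reps


def sip_threshold(
    image: np.ndarray,
    size_interval: tuple[float, float] | None = None,
    config: SegConfig | None = None,
    voxel_size=None,
) -> SipResult:
    """Choose the global threshold by the SizeIntervalPrecision criterion.

    Every candidate grey level T is evaluated on the components of
    ``{I >= T}``; the winner maximises the number of components with
    physical volume inside ``size_interval`` (µm³), with ties broken by
    maximal precision and then by the lowest T. With
    ``config.sip_objective == "precision-first"`` the precision is
    maximised first instead.

    The sweep is computed incrementally on the max-tree: a component of
    ``{I >= T}`` is exactly the subtree of a node whose level range
    contains T, so per-level counts are range updates over the candidate
    levels rather than one labelling per level.
    """
    config = config or SegConfig()
    if size_interval is None:
        size_interval = (config.sip_min_volume_um3, config.sip_max_volume_um3)
    vmin_um3, vmax_um3 = size_interval
    if not vmin_um3 < vmax_um3:
        raise ValueError("size interval must satisfy min < max")
    voxel_size = tuple(voxel_size if voxel_size is not None else config.voxel_size)
    image = np.asarray(image)
    if image.size == 0:
        raise NoConformingThreshold("empty image")
    voxvol = float(np.prod(voxel_size))

    work, levels = _bin_levels(image, config.sip_max_levels)
    n_levels = len(levels)
    if n_levels < 2:
        raise NoConformingThreshold("image is flat; no meaningful threshold exists")
    tree = ComponentTree(work, config.connectivity, voxel_size, need_moments=False)
    sizes = tree.node_sizes()
    node_level_idx = np.searchsorted(levels, tree.level)
    parent_level_idx = np.searchsorted(levels, tree.level[tree.node_parent])
    parent_level_idx[tree.root_node] = -1  # root spans every level <= its own

    conforming = (sizes * voxvol >= vmin_um3) & (sizes * voxvol <= vmax_um3)
    count_diff = np.zeros(n_levels + 1, np.int64)
    voxel_diff = np.zeros(n_levels + 1, np.int64)
    lo = parent_level_idx[conforming] + 1
    hi = node_level_idx[conforming]
    np.add.at(count_diff, lo, 1)
    np.add.at(count_diff, hi + 1, -1)
    np.add.at(voxel_diff, lo, sizes[conforming])
    np.add.at(voxel_diff, hi + 1, -sizes[conforming])
    n_conf = np.cumsum(count_diff[:-1])
    conf_vox = np.cumsum(voxel_diff[:-1])

    level_of = np.searchsorted(levels, work.ravel())
    hist = np.bincount(level_of, minlength=n_levels)
    total_fg = hist[::-1].cumsum()[::-1]
    precision = np.where(total_fg > 0, conf_vox / np.maximum(total_fg, 1), 0.0)

    if n_conf.max() == 0:
        raise NoConformingThreshold(
            f"no threshold yields a component with volume in [{vmin_um3}, {vmax_um3}] µm³"
        )
    if config.sip_objective == "precision-first":
        keys = (precision, n_conf)
    else:
        keys = (n_conf, precision)
    best = np.flatnonzero(keys[0] == keys[0].max())
    best = best[keys[1][best] == keys[1][best].max()]
    win = int(best.min())  # lowest threshold among remaining ties
    threshold = float(levels[win])
    return SipResult(
        threshold=threshold,
        n_conforming=int(n_conf[win]),
        precision=float(precision[win]),
        mask=image >= threshold,
    )


def distance_map_seeds(
    mask: np.ndarray,
    voxel_size=(2.0, 0.31, 0.31),
    smoothing_sigma_um: float = 1.0,
    connectivity: int = 6,
    h_maxima_um: float = 0.0,
) -> LabelVolume:
    """Seeds for the nucleus watershed: regional maxima of the distance map.

    The Euclidean distance transform of the mask (physically scaled,
    optionally Gaussian-smoothed to suppress maxima created by boundary
    roughness) is searched for regional maxima; a connected plateau of
    equal distance collapses to the single plateau voxel nearest its
    centroid, so flat-topped regions yield one seed, not many. With
    ``h_maxima_um > 0`` maxima shallower than that depth relative to
    their separating saddle are merged (suppresses double seeds from
    residual boundary roughness inside one nucleus).
    """
    mask = np.asarray(mask).astype(bool)
    seeds = np.zeros(mask.shape, np.int32)
    if not mask.any():
        return LabelVolume(seeds, voxel_size)
    voxel_size = np.asarray(voxel_size, float)
    edt = ndimage.distance_transform_edt(mask, sampling=voxel_size)
    if smoothing_sigma_um > 0:
        edt = ndimage.gaussian_filter(edt, sigma=smoothing_sigma_um / voxel_size)
        edt[~mask] = 0.0
    conn = 1 if connectivity == 6 else 3
    if h_maxima_um > 0:
        peaks = h_maxima(edt, h_maxima_um).astype(bool) & mask
    else:
        peaks = local_maxima(edt, connectivity=conn) & mask
    plateaus, n_plat = ndimage.label(peaks, structure=_structure(connectivity))
    lab = 0
    for sl, plab in zip(ndimage.find_objects(plateaus), range(1, n_plat + 1)):
        coords = np.argwhere(plateaus[sl] == plab) + np.array([s.start for s in sl])
        centroid = coords.mean(axis=0)
        pick = coords[np.argmin(((coords - centroid) ** 2).sum(axis=1))]
        lab += 1
        seeds[tuple(pick)] = lab
    return LabelVolume(seeds, tuple(voxel_size))


def segment_nuclei(
    image: np.ndarray,
    config: SegConfig | None = None,
    voxel_size=None,
) -> LabelVolume:
    """Segment all nuclei in a DAPI channel.

    SIP global threshold → distance-map seeds → seeded watershed split;
    components smaller than ``config.debris_floor_um3`` are dropped as
    debris and the labels compacted.
    """
    config = config or SegConfig()
    voxel_size = tuple(voxel_size if voxel_size is not None else config.voxel_size)
    sip = sip_threshold(image, None, config, voxel_size)
    seeds = distance_map_seeds(
        sip.mask,
        voxel_size,
        config.seed_smoothing_sigma_um,
        config.connectivity,
        config.seed_h_maxima_um,
    )
    split = watershed_split(sip.mask, seeds, voxel_size, config.connectivity)
    labels = split.labels
    voxvol = float(np.prod(voxel_size))
    counts = np.bincount(labels.ravel())
    debris = np.flatnonzero(counts * voxvol < config.debris_floor_um3)
    debris = debris[debris > 0]
    if len(debris):
        labels = np.where(np.isin(labels, debris), 0, labels)
        logger.info("segment_nuclei: removed %d debris component(s)", len(debris))
    return LabelVolume(relabel_contiguous(labels), voxel_size)
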