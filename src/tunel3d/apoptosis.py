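"""Apoptotic-nucleus calling and per-embryo metrics.

An apoptotic nucleus is a nucleus inside the blastocyst area that is
stained by both DAPI and TUNEL: each segmented TUNEL object is assigned
to the nucleus sharing the most voxels with it, the assignment counting
only if the overlap dominates the TUNEL object and the nucleus sits in
the blastocyst area. TUNEL signal with no DAPI support underneath is
discarded, never counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import convex_hull_image

from .io_stacks import LabelVolume, SegConfig
from .poe3d import PoeResult

logger = logging.getLogger("tunel3d")


@dataclass
class EmbryoMetrics:
    """Per-embryo nucleus / apoptosis counts."""

    embryo_id: str
    treatment: str
    replicate: int
    n_nuclei: int
    n_apoptotic: int
    prop_apoptotic: float  # NaN when n_nuclei == 0
    excluded: bool = False
    exclusion_reason: str = ""


def blastocyst_area(nuclei: LabelVolume, config: SegConfig | None = None) -> np.ndarray:
    """Binary blastocyst area: convex hull of all nuclei, dilated.

    The dilation radius is ``config.area_dilation_radii`` mean nucleus
    radii (equivalent-sphere radius of the mean nucleus volume), so the
    area hugs the embryo rather than the nucleus centroids alone.
    """
    config = config or SegConfig()
    labels = nuclei.labels
    if labels.max() == 0:
        raise ValueError("blastocyst_area requires at least one nucleus")
    binary = labels > 0
    hull = convex_hull_image(binary)
    voxvol = float(np.prod(nuclei.voxel_size))
    counts = np.bincount(labels.ravel())[1:]
    mean_vol = counts[counts > 0].mean() * voxvol
    radius = config.area_dilation_radii * (3.0 * mean_vol / (4.0 * np.pi)) ** (1.0 / 3.0)
    if radius <= 0:
        return hull
    outside = ndimage.distance_transform_edt(~hull, sampling=nuclei.voxel_size)
    return hull | (outside <= radius)


def call_apoptotic(
    nuclei: LabelVolume,
    tunel: PoeResult | LabelVolume,
    area: np.ndarray | None = None,
    overlap_fraction: float = 0.5,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag nuclei co-labelled by TUNEL objects.

    Returns ``(flags, assignments)`` where ``flags[k]`` is True when
    nucleus label ``k`` is apoptotic (index 0 unused), and
    ``assignments`` records, per TUNEL object, the best-overlap nucleus,
    the overlap voxel count, validity and a discard reason
    (``no-DAPI`` / ``outside-area`` / ``weak-overlap``) when invalid.
    """
    tunel_labels = tunel.objects.labels if isinstance(tunel, PoeResult) else tunel.labels
    nuc = nuclei.labels
    if nuc.shape != tunel_labels.shape:
        raise ValueError("nucleus and TUNEL label volumes have different shapes")
    if area is not None and area.shape != nuc.shape:
        raise ValueError("area mask has a different shape")

    n_nuc = int(nuc.max())
    n_tun = int(tunel_labels.max())
    flags = np.zeros(n_nuc + 1, bool)
    rows = []
    if n_tun == 0 or n_nuc == 0:
        if n_tun and n_nuc == 0:
            for t in range(1, n_tun + 1):
                rows.append(
                    {"tunel_label": t, "nucleus_label": 0, "overlap_voxels": 0,
                     "valid": False, "reason": "no-DAPI"}
                )
        return flags, pd.DataFrame(
            rows, columns=["tunel_label", "nucleus_label", "overlap_voxels", "valid", "reason"]
        )

    # joint histogram of (tunel label, nucleus label) over TUNEL voxels
    tmask = tunel_labels > 0
    pair = tunel_labels[tmask].astype(np.int64) * (n_nuc + 1) + nuc[tmask].astype(np.int64)
    joint = np.bincount(pair, minlength=(n_tun + 1) * (n_nuc + 1)).reshape(
        n_tun + 1, n_nuc + 1
    )
    tunel_volumes = joint.sum(axis=1)

    # nucleus centroid inside area?
    centroid_in_area = np.ones(n_nuc + 1, bool)
    if area is not None:
        centroids = ndimage.center_of_mass(nuc > 0, nuc, index=range(1, n_nuc + 1))
        for k, c in enumerate(centroids, start=1):
            centroid_in_area[k] = bool(area[tuple(np.round(c).astype(int))])

    for t in range(1, n_tun + 1):
        overlaps = joint[t, 1:]
        if overlaps.sum() == 0:
            rows.append({"tunel_label": t, "nucleus_label": 0, "overlap_voxels": 0,
                         "valid": False, "reason": "no-DAPI"})
            continue
        best = int(np.argmax(overlaps)) + 1
        shared = int(overlaps[best - 1])
        if shared < overlap_fraction * tunel_volumes[t]:
            rows.append({"tunel_label": t, "nucleus_label": best, "overlap_voxels": shared,
                         "valid": False, "reason": "weak-overlap"})
        elif not centroid_in_area[best]:
            rows.append({"tunel_label": t, "nucleus_label": best, "overlap_voxels": shared,
                         "valid": False, "reason": "outside-area"})
        else:
            flags[best] = True
            rows.append({"tunel_label": t, "nucleus_label": best, "overlap_voxels": shared,
                         "valid": True, "reason": ""})
    return flags, pd.DataFrame(rows)


def compute_metrics(
    nuclei: LabelVolume, flags: np.ndarray, metadata: Mapping | None = None
) -> EmbryoMetrics:
    """Collapse a segmentation + apoptosis flags into one metrics row."""
    metadata = dict(metadata or {})
    n_nuclei = int(nuclei.labels.max())
    n_apoptotic = int(np.asarray(flags)[1:].sum()) if len(flags) > 1 else 0
    if n_apoptotic > n_nuclei:
        raise ValueError("more apoptotic flags than nuclei")
    prop = n_apoptotic / n_nuclei if n_nuclei > 0 else float("nan")
    return EmbryoMetrics(
        embryo_id=str(metadata.get("embryo_id", "")),
        treatment=str(metadata.get("treatment", "control")),
        replicate=int(metadata.get("replicate", 1)),
        n_nuclei=n_nuclei,
        n_apoptotic=n_apoptotic,
        prop_apoptotic=prop,
        excluded=n_nuclei == 0,
        exclusion_reason="no nuclei" if n_nuclei == 0 else "",
    )


def apply_exclusions(
    metrics: pd.DataFrame, qc_grades: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop dead/degenerated embryos (quality grade 4) from a metrics table.

    ``qc_grades`` must provide a grade for every row (1 best … 4 dead or
    degenerating; half grades allowed); a missing grade raises, naming
    the offending row. Returns ``(kept, excluded)`` with
    ``len(kept) + len(excluded) == len(metrics)``.
    """
    qc = pd.Series(qc_grades).reindex(metrics.index)
    missing = qc.index[qc.isna()]
    if len(missing):
        ident = metrics.loc[missing[0]].get("embryo_id", missing[0])
        raise ValueError(f"missing QC grade for row {ident!r}")
    dead = qc >= 4.0
    kept = metrics.loc[~dead].copy()
    excluded = metrics.loc[dead].copy()
    if len(excluded):
        excluded["excluded"] = True
        excluded["exclusion_reason"] = "dead/degenerated (grade 4)"
        logger.info("excluded %d dead/degenerated embryo(s), %d retained",
                    len(excluded), len(kept))
    if len(kept) == 0:
        logger.warning("apply_exclusions: all embryos excluded")
    return kept, excluded
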