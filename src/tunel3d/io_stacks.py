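"""Stack and table I/O, configuration, and the pipeline driver.

Conventions used throughout the package: axes are (z, y, x), 0-based;
physical units are micrometres (µm); all size criteria are specified in
physical units and converted to voxels with the stack's ``voxel_size``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("tunel3d")

DEFAULT_CHANNELS = ("DAPI", "TUNEL")


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass
class VoxelStack:
    """A multi-channel 3D fluorescence stack.

    Parameters
    ----------
    data : ndarray, shape (C, Z, Y, X)
        Non-negative integer intensities, one volume per channel.
    channels : sequence of str
        Channel names in the order of ``data``'s first axis
        (typically ``("DAPI", "TUNEL")``).
    voxel_size : (float, float, float)
        Physical voxel size in µm for (z, y, x). The study images used
        2 µm optical sections, hence the default z spacing.
    bit_depth : int
        8 or 16.
    """

    data: np.ndarray
    channels: Sequence[str] = DEFAULT_CHANNELS
    voxel_size: tuple[float, float, float] = (2.0, 0.31, 0.31)
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise FormatError(
                f"stack data must be (C, Z, Y, X); got shape {self.data.shape}"
            )
        if len(self.channels) != self.data.shape[0]:
            raise FormatError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} channels"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.data.min() < 0 or self.data.max() > 2**self.bit_depth - 1:
            raise ValueError("intensities outside bit-depth range")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = list(self.channels).index(name)
        except ValueError:
            raise FormatError(f"channel {name!r} not present in {list(self.channels)}")
        return self.data[idx]


@dataclass
class LabelVolume:
    """Integer-labelled 3D segmentation aligned with a :class:`VoxelStack`.

    0 is background; objects are labelled 1..K with contiguous positive
    integers, each non-empty.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 0.31, 0.31)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def validate(self) -> None:
        present = np.unique(self.labels)
        present = present[present > 0]
        if len(present) and not np.array_equal(present, np.arange(1, len(present) + 1)):
            raise ValueError("labels are not contiguous 1..K")


def relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Map the positive labels of ``labels`` onto 1..K preserving order."""
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int64) if labels.size else None
    if lut is None or len(present) == 0:
        return np.zeros_like(labels, dtype=np.int32)
    lut[present] = np.arange(1, len(present) + 1)
    return lut[labels].astype(np.int32)


@dataclass
class SegConfig:
    """All segmentation-algorithm parameters with their defaults.

    Size criteria are physical (µm / µm³). The diameter bounds select
    TUNEL objects in the per-object ellipsoid-fit step; the SIP volume
    interval selects nucleus-sized components for global thresholding.
    """

    # POE (TUNEL channel)
    min_diameter_um: float = 3.0
    max_diameter_um: float = 12.0
    min_fit_score: float = 0.5
    fit_score_tolerance: float = 0.05
    erosion_voxels: int = 2
    max_iterations: int = 10
    # SIP (DAPI channel)
    sip_min_volume_um3: float = 80.0
    sip_max_volume_um3: float = 800.0
    sip_objective: str = "precision-first"  # or "count"
    sip_max_levels: int = 1024
    debris_floor_um3: float = 10.0
    seed_smoothing_sigma_um: float = 0.5
    seed_h_maxima_um: float = 0.3
    # apoptosis calling
    tunel_overlap_fraction: float = 0.3
    use_blastocyst_area: bool = True
    area_dilation_radii: float = 1.0
    # shared
    connectivity: int = 6  # 6 or 26 neighbourhood in 3D
    channel_map: dict = field(default_factory=lambda: {"DAPI": 0, "TUNEL": 1})
    voxel_size: tuple[float, float, float] = (2.0, 0.31, 0.31)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not self.min_diameter_um < self.max_diameter_um:
            raise ValueError("min_diameter_um must be < max_diameter_um")
        if not self.sip_min_volume_um3 < self.sip_max_volume_um3:
            raise ValueError("sip_min_volume_um3 must be < sip_max_volume_um3")
        if self.erosion_voxels < 0:
            raise ValueError("erosion_voxels must be >= 0")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if not 0.0 <= self.tunel_overlap_fraction <= 1.0:
            raise ValueError("tunel_overlap_fraction must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SegConfig":
        """Load a config from a sectioned YAML file; sections are flattened."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, dict) and key != "channel_map":
                flat.update(value)
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "voxel_size" in flat:
            flat["voxel_size"] = tuple(float(v) for v in flat["voxel_size"])
        return cls(**flat)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["voxel_size"] = list(self.voxel_size)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# stack / label I/O


def read_stack(
    path: str | Path,
    channel_map: Mapping[str, int] | None = None,
    voxel_size: tuple[float, float, float] | None = None,
) -> VoxelStack:
    """Read a TIFF / OME-TIFF z-stack into a :class:`VoxelStack`.

    ``channel_map`` names the channels to extract (name → index along the
    channel axis). The voxel size is taken from OME ``PhysicalSize*``
    metadata when present, otherwise from ``voxel_size`` (falling back to
    the package default).
    """
    channel_map = dict(channel_map or {"DAPI": 0, "TUNEL": 1})
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            axes = series.axes
            arr = series.asarray()
            meta_voxel = _ome_voxel_size(tf)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"{path.name}: not a readable TIFF ({exc})") from None

    arr = _to_czyx(arr, axes, path.name)
    n_channels = arr.shape[0]
    for name, idx in channel_map.items():
        if idx >= n_channels:
            raise FormatError(
                f"{path.name}: channel {name!r} maps to index {idx} but file has "
                f"{n_channels} channel(s)"
            )
    names = sorted(channel_map, key=channel_map.get)
    data = np.stack([arr[channel_map[name]] for name in names])
    vs = meta_voxel or voxel_size or (2.0, 0.31, 0.31)
    bit_depth = 16 if data.dtype.itemsize > 1 else 8
    return VoxelStack(data=data, channels=names, voxel_size=tuple(vs), bit_depth=bit_depth)


def _to_czyx(arr: np.ndarray, axes: str, name: str) -> np.ndarray:
    """Reorder a tifffile series to (C, Z, Y, X), adding missing axes."""
    axes = axes.upper().replace("S", "C").replace("Q", "Z").replace("I", "Z")
    if arr.ndim == 2:
        arr, axes = arr[None, None], "CZYX"
    elif arr.ndim == 3:
        if "C" in axes and "Z" not in axes:
            order = [axes.index(a) for a in "CYX"]
            arr, axes = arr.transpose(order)[:, None], "CZYX"
        else:
            arr, axes = arr[None], "CZYX"
    elif arr.ndim == 4:
        if not set("CZYX") <= set(axes):
            raise FormatError(f"{name}: unsupported axis layout {axes!r}")
        arr = arr.transpose([axes.index(a) for a in "CZYX"])
        axes = "CZYX"
    else:
        raise FormatError(f"{name}: unsupported {arr.ndim}-D layout {axes!r}")
    return arr


def _ome_voxel_size(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    try:
        import xml.etree.ElementTree as ET

        if not tf.ome_metadata:
            return None
        root = ET.fromstring(tf.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        pixels = root.find(".//ome:Pixels", ns)
        if pixels is None:
            return None
        sizes = [pixels.get(f"PhysicalSize{a}") for a in "ZYX"]
        if any(s is None for s in sizes):
            return None
        return tuple(float(s) for s in sizes)
    except Exception:  # malformed metadata is not fatal
        return None


def write_stack(stack: VoxelStack, path: str | Path) -> None:
    """Write a :class:`VoxelStack` as OME-TIFF with physical-size metadata."""
    vz, vy, vx = stack.voxel_size
    tifffile.imwrite(
        Path(path),
        stack.data,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": vz,
            "PhysicalSizeY": vy,
            "PhysicalSizeX": vx,
            "Channel": {"Name": list(stack.channels)},
        },
        ome=True,
    )


def write_labels(labels: LabelVolume, path: str | Path) -> None:
    """Write a label volume as TIFF; 16-bit, or 32-bit when K > 65535."""
    k = labels.n_labels
    dtype = np.uint32 if k > 65535 else np.uint16
    tifffile.imwrite(Path(path), labels.labels.astype(dtype), metadata={"axes": "ZYX"})


def read_labels(
    path: str | Path, voxel_size: tuple[float, float, float] = (2.0, 0.31, 0.31)
) -> LabelVolume:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return LabelVolume(labels=arr.astype(np.int64), voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# tabular I/O


#: canonical column names for the developmental workbook reader
DEV_COLUMNS = (
    "replicate",
    "treatment",
    "n_oocytes",
    "cleaved",
    "cleaved_gt2",
    "blastocyst_d5",
    "blastocyst_d6",
)


def read_dev_workbook(
    path: str | Path,
    column_map: Mapping[str, str],
    sheet: str | int = 0,
) -> pd.DataFrame:
    """Read a developmental-outcomes XLSX sheet with a user-supplied mapping.

    The deposited study workbook's exact layout is not standardised, so the
    reader is mapping-driven: ``column_map`` maps canonical names (see
    :data:`DEV_COLUMNS` for group-level tables, or any other schema used by
    the stats layer) to the spreadsheet's column headers.
    """
    df = pd.read_excel(Path(path), sheet_name=sheet, engine="openpyxl")
    missing = [src for src in column_map.values() if src not in df.columns]
    if missing:
        raise FormatError(f"workbook is missing mapped columns: {missing}")
    out = df[[column_map[k] for k in column_map]].copy()
    out.columns = list(column_map)
    return out


METRICS_COLUMNS = (
    "embryo_id",
    "treatment",
    "replicate",
    "n_nuclei",
    "n_apoptotic",
    "prop_apoptotic",
    "excluded",
    "exclusion_reason",
)


# ---------------------------------------------------------------------------
# pipeline driver


def run_pipeline(
    config_path: str | Path,
    input_dir: str | Path,
    output_dir: str | Path,
) -> pd.DataFrame:
    """Segment every stack in ``input_dir`` and write metrics + model report.

    Looks for ``*.tif``/``*.tiff`` stacks and an optional ``metadata.csv``
    sidecar (columns embryo_id, treatment, replicate, grade). A failing
    stack is logged and skipped; the run fails only if no stack succeeds.
    Deterministic for fixed config and inputs.
    """
    from . import apoptosis, nuclei_seg, poe3d, stats

    config = SegConfig.from_yaml(config_path)
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(list(input_dir.glob("*.tif")) + list(input_dir.glob("*.tiff")))
    if not paths:
        raise FormatError(f"no TIFF stacks found in {input_dir}")

    meta = None
    meta_path = input_dir / "metadata.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path).set_index("embryo_id")

    rows = []
    for path in paths:
        embryo_id = path.stem
        try:
            stack = read_stack(path, config.channel_map, config.voxel_size)
            logger.info("segmenting %s (shape %s)", embryo_id, stack.shape)
            nuclei = nuclei_seg.segment_nuclei(stack.channel("DAPI"), config)
            tunel = poe3d.iterative_poe_segment(
                stack.channel("TUNEL"), config, voxel_size=stack.voxel_size
            )
            area = (
                apoptosis.blastocyst_area(nuclei, config)
                if config.use_blastocyst_area and nuclei.n_labels
                else np.ones(stack.shape, bool)
            )
            flags, _ = apoptosis.call_apoptotic(
                nuclei, tunel, area, config.tunel_overlap_fraction
            )
            info = meta.loc[embryo_id].to_dict() if meta is not None and embryo_id in meta.index else {}
            metrics = apoptosis.compute_metrics(
                nuclei,
                flags,
                {
                    "embryo_id": embryo_id,
                    "treatment": info.get("treatment", "control"),
                    "replicate": info.get("replicate", 1),
                    "grade": info.get("grade", 1.0),
                },
            )
            rows.append(dataclasses.asdict(metrics) | {"grade": info.get("grade", 1.0)})
            write_labels(nuclei, output_dir / f"{embryo_id}_nuclei.tif")
            write_labels(tunel.objects, output_dir / f"{embryo_id}_tunel.tif")
            logger.info(
                "%s: %d nuclei, %d apoptotic", embryo_id, metrics.n_nuclei, metrics.n_apoptotic
            )
        except Exception as exc:  # per-embryo isolation
            logger.warning("embryo %s failed: %s", embryo_id, exc)
    if not rows:
        raise RuntimeError("all embryos failed; see log")

    table = pd.DataFrame(rows)
    table, excluded = apoptosis.apply_exclusions(table, table["grade"])
    table.to_csv(output_dir / "metrics.csv", index=False)
    excluded.to_csv(output_dir / "metrics_excluded.csv", index=False)

    report = None
    if table["treatment"].nunique() >= 2 and len(table) >= 10:
        try:
            fits = stats.fit_count_models(table)
            report = pd.concat([f.to_frame() for f in fits.values()])
            report.to_csv(output_dir / "model_report.csv", index=False)
        except Exception as exc:
            logger.warning("count models not fitted: %s", exc)
    return table
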