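"""Volume / vector-field I/O and run configuration.

Axis convention (used everywhere in this package)
-------------------------------------------------
Image arrays are indexed ``(Z, Y, X)``: Z is the optical axis of the
microscope (plane index in the TIFF stack), Y is the longitudinal axis of
the tissue strip (the traction axis), X the remaining lateral axis.
Direction vectors are stored as ``[vz, vy, vx]`` so that vector components
line up with array axes; on-disk tables use explicitly named ``vx, vy, vz``
columns.

Voxel metadata is carried as ``(dx, dy, dz)`` in micrometres, default
``(0.44, 0.44, 2.0)`` — the lateral pixel size and axial step of the
two-photon acquisition this pipeline targets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("myodisarray")
if not logger.handlers:  # library default: timestamped messages on stderr
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

DEFAULT_VOXEL = (0.44, 0.44, 2.0)  # (dx, dy, dz) um


@dataclasses.dataclass
class Volume:
    """A 3D grayscale image volume with voxel-size metadata.

    Parameters
    ----------
    data
        Intensity grid, axis order (Z, Y, X). Unsigned 8-bit on input,
        float internally after equalization.
    voxel
        Voxel size ``(dx, dy, dz)`` in micrometres.
    """

    data: np.ndarray
    voxel: tuple[float, float, float] = DEFAULT_VOXEL

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if any(v <= 0 for v in self.voxel):
            raise ValueError("voxel sizes must be positive")

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        """Voxel size reordered to array axis order (dz, dy, dx)."""
        dx, dy, dz = self.voxel
        return (dz, dy, dx)

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (Z, Y, X) in micrometres."""
        return tuple(n * d for n, d in zip(self.data.shape, self.spacing_zyx))


@dataclasses.dataclass
class RunConfig:
    """All tunable parameters of the pipeline, with the published defaults.

    A bare ``RunConfig()`` reproduces the reference settings: CLAHE clip
    0.08, K=4 intensity clusters, 16-um analysis chunks accepted at >=80%
    tissue, sarcomere period band 1.6-2.0 um, reliability threshold 14% of
    the normalized Sratio range, macrovoxel scales m=2..6, 10-um map
    smoothing.
    """

    clip_limit: float = 0.08
    k_clusters: int = 4
    chunk_um: float = 16.0
    tissue_fraction_min: float = 0.80
    period_range_um: tuple[float, float] = (1.6, 2.0)
    sratio_threshold: float = 0.14
    macrovoxel_m_list: tuple[int, ...] = (2, 3, 4, 5, 6)
    map_smooth_sigma_um: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("clip_limit", "tissue_fraction_min", "sratio_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        lo, hi = self.period_range_um
        if not lo < hi:
            raise ValueError("period_range_um must be (low, high) with low < high")
        if any(m < 2 for m in self.macrovoxel_m_list):
            raise ValueError("macrovoxel m values must be >= 2")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat key:value YAML config; unknown keys are an error."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("period_range_um", "macrovoxel_m_list"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["period_range_um"] = list(d["period_range_um"])
        d["macrovoxel_m_list"] = list(d["macrovoxel_m_list"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# volumes

def read_volume(path: str | Path, voxel: Sequence[float] = DEFAULT_VOXEL) -> Volume:
    """Read a multi-page TIFF (or a directory of per-plane TIFFs) as a Volume.

    Planes in a directory are stacked in filename sort order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF planes in {path}")
        planes = [tifffile.imread(f) for f in files]
        shapes = {p.shape for p in planes}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent plane shapes: {sorted(shapes)}")
        data = np.stack([np.atleast_2d(p) for p in planes], axis=0)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    if data.dtype not in (np.uint8, np.uint16, np.float32, np.float64):
        raise ValueError(f"unsupported bit depth: {data.dtype}")
    return Volume(data, tuple(voxel))


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a Volume as a multi-page grayscale TIFF (dtype preserved)."""
    tifffile.imwrite(Path(path), volume.data, photometric="minisblack")


# ---------------------------------------------------------------------------
# vector fields

#: columns of the on-disk vector-field table, one row per analysis chunk
FIELD_COLUMNS = [
    "iz", "iy", "ix",            # chunk grid indices
    "cz_um", "cy_um", "cx_um",   # chunk centre, micrometres
    "vx", "vy", "vz",            # unit direction (zero if not extracted)
    "frequency_um1",             # Z-band spatial frequency, 1/um
    "period_um",                 # sarcomere period, um
    "sratio_raw", "sratio_norm",
    "is_tissue", "is_reliable", "is_outlier",
]


def write_vector_field(field, path: str | Path) -> None:
    """Persist a VectorField as a TSV table (6 significant digits).

    One row per chunk of the analysis grid; lossless round trip at the
    stated precision via :func:`read_vector_field`.
    """
    rows = []
    for rec in field.records.ravel():
        vz, vy, vx = rec.direction
        cz, cy, cx = rec.center_um
        rows.append((*rec.index, cz, cy, cx, vx, vy, vz,
                     rec.frequency, rec.period, rec.sratio_raw,
                     rec.sratio_norm, int(rec.is_tissue),
                     int(rec.is_reliable), int(rec.is_outlier)))
    df = pd.DataFrame(rows, columns=FIELD_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_vector_field(path: str | Path):
    """Read a vector-field TSV written by :func:`write_vector_field`."""
    from .orientation import OrientationRecord, VectorField

    df = pd.read_csv(path, sep="\t")
    shape = tuple(int(df[c].max()) + 1 for c in ("iz", "iy", "ix"))
    records = np.empty(shape, dtype=object)
    for row in df.itertuples(index=False):
        rec = OrientationRecord(
            index=(int(row.iz), int(row.iy), int(row.ix)),
            center_um=(row.cz_um, row.cy_um, row.cx_um),
            direction=np.array([row.vz, row.vy, row.vx]),
            frequency=row.frequency_um1,
            period=row.period_um,
            sratio_raw=row.sratio_raw,
            sratio_norm=row.sratio_norm,
            is_tissue=bool(row.is_tissue),
            is_reliable=bool(row.is_reliable),
            is_outlier=bool(row.is_outlier),
        )
        records[rec.index] = rec
    return VectorField(records=records)


def write_summary(summary: dict, path: str | Path) -> None:
    """Write the run summary (global statistics, fits, counts) as JSON."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=_default)
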