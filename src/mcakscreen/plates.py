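"""Plate layouts, well readings, fluorescence images and run configuration.

Every downstream stage consumes the types defined here.  A plate is a map
from well ids (row letter + 1-based column, e.g. ``"A1"``) to a role:
control wells (FCP, FMCAK, FMCAK+antibody, FMCAK+Aurora B, buffer blank)
or compound wells carrying a compound id.  Readings are per-well,
per-channel reader intensities; images are calibrated 2-D grayscale
intensity grids.
"""

from __future__ import annotations

import enum
import re
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "WellRole",
    "Channel",
    "WellAssignment",
    "PlateLayout",
    "WellReading",
    "FluorescenceImage",
    "RunConfig",
    "well_id",
    "parse_well",
    "builtin_layout",
    "read_plate_map",
    "write_plate_map",
    "read_well_images",
    "write_well_images",
    "read_results",
    "write_results",
    "subseed",
]


class WellRole(str, enum.Enum):
    """Role of a well on an assay plate."""

    FCP_CONTROL = "FCP_CONTROL"          # donor-acceptor fusion, maximal FRET / no enzyme
    FMCAK_CONTROL = "FMCAK_CONTROL"      # uninhibited enzyme
    ANTIBODY_CONTROL = "ANTIBODY_CONTROL"  # enzyme + inhibitory antibody
    AURORA_CONTROL = "AURORA_CONTROL"    # enzyme pre-phosphorylated by Aurora B
    BUFFER_BLANK = "BUFFER_BLANK"        # buffer only, used for background correction
    COMPOUND = "COMPOUND"                # library compound + enzyme


class Channel(str, enum.Enum):
    """Reader emission channel."""

    FRET_EM = "FRET_EM"        # donor excitation, acceptor emission (I_F)
    DONOR_EM = "DONOR_EM"      # donor excitation, donor emission (I_D)
    ACCEPTOR_EM = "ACCEPTOR_EM"  # acceptor excitation, acceptor emission


_WELL_RE = re.compile(r"^([A-P])(\d{1,2})$")

_FORMAT_DIMS = {96: (8, 12), 384: (16, 24)}  # rows x columns


def well_id(row: int, col: int) -> str:
    """Build a well id from 0-based row and column indices."""
    return f"{chr(ord('A') + row)}{col + 1}"


def parse_well(well: str, plate_format: int | None = None) -> tuple[int, int]:
    """Parse a well id into 0-based (row, column); validate against format."""
    m = _WELL_RE.match(well.strip().upper())
    if not m:
        raise ValueError(f"malformed well id: {well!r}")
    row = ord(m.group(1)) - ord("A")
    col = int(m.group(2)) - 1
    if col < 0:
        raise ValueError(f"malformed well id: {well!r}")
    if plate_format is not None:
        n_rows, n_cols = _FORMAT_DIMS[plate_format]
        if row >= n_rows or col >= n_cols:
            raise ValueError(
                f"well {well!r} outside a {plate_format}-well plate"
            )
    return row, col


@dataclass(frozen=True)
class WellAssignment:
    role: WellRole
    compound_id: str = ""


@dataclass(frozen=True)
class PlateLayout:
    """Assignment of roles (and compound ids) to wells of a 96/384 plate."""

    format: int
    wells: dict[str, WellAssignment]

    def __post_init__(self) -> None:
        if self.format not in _FORMAT_DIMS:
            raise ValueError(f"plate format must be 96 or 384, got {self.format}")
        for w, a in self.wells.items():
            parse_well(w, self.format)
            if a.role is WellRole.COMPOUND and not a.compound_id:
                raise ValueError(f"compound well {w} has no compound_id")
            if a.role is not WellRole.COMPOUND and a.compound_id:
                raise ValueError(f"control well {w} carries a compound_id")

    def wells_with_role(self, role: WellRole) -> list[str]:
        return sorted(
            (w for w, a in self.wells.items() if a.role is role),
            key=lambda w: parse_well(w),
        )

    @property
    def compound_wells(self) -> dict[str, str]:
        """Map well -> compound id for all compound wells."""
        return {
            w: a.compound_id
            for w, a in self.wells.items()
            if a.role is WellRole.COMPOUND
        }

    def role_counts(self) -> dict[WellRole, int]:
        counts: dict[WellRole, int] = {}
        for a in self.wells.values():
            counts[a.role] = counts.get(a.role, 0) + 1
        return counts


@dataclass(frozen=True)
class WellReading:
    """One reader intensity for one (well, channel) pair."""

    well: str
    channel: Channel
    intensity: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.intensity) or self.intensity < 0:
            raise ValueError(
                f"intensity for {self.well}/{self.channel.value} must be "
                f"finite and >= 0, got {self.intensity}"
            )


@dataclass
class FluorescenceImage:
    """2-D grayscale intensity grid with pixel-size calibration.

    ``pixel_size`` is in calibration length units per pixel.  The default
    12-bit depth uses the camera convention of 4094 usable grayscale
    levels.
    """

    pixels: np.ndarray
    bit_depth: int = 12
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("image must be a 2-D grid")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.pixels.min() < 0 or self.pixels.max() > self.max_gray:
            raise ValueError("intensities must lie within the bit depth range")

    @property
    def max_gray(self) -> int:
        return 2 ** self.bit_depth - 2

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _role(value: str) -> WellRole:
    try:
        return WellRole(value.strip())
    except ValueError as exc:
        raise ValueError(f"unknown well role: {value!r}") from exc


# ---------------------------------------------------------------------------
# Built-in pilot layouts.
#
# 96-well pilot: FCP in column 1 (A1-H1), FMCAK in A12-D12, FMCAK+antibody
# in E12-H12, compounds in columns 2-11.
# 384-well pilot: FCP in B1-P1, FMCAK in B24-H24, FMCAK+antibody in
# I24-P24, compounds in columns 2-23.
# ---------------------------------------------------------------------------

def builtin_layout(name: str, compound_ids: list[str] | None = None) -> PlateLayout:
    """Return a named built-in plate layout.

    Parameters
    ----------
    name:
        ``"pilot96"`` or ``"pilot384"``.
    compound_ids:
        Optional ids for the compound wells, assigned column-major
        (column 2 top-to-bottom, then column 3, ...).  Wells beyond the
        supplied ids are omitted from the layout.  Defaults to placeholder
        ids ``cpd-<well>``.
    """
    wells: dict[str, WellAssignment] = {}
    if name == "pilot96":
        fmt = 96
        for r in range(8):
            wells[well_id(r, 0)] = WellAssignment(WellRole.FCP_CONTROL)
        for r in range(4):
            wells[well_id(r, 11)] = WellAssignment(WellRole.FMCAK_CONTROL)
        for r in range(4, 8):
            wells[well_id(r, 11)] = WellAssignment(WellRole.ANTIBODY_CONTROL)
        compound_cols = range(1, 11)
        n_rows = 8
    elif name == "pilot384":
        fmt = 384
        for r in range(1, 16):
            wells[well_id(r, 0)] = WellAssignment(WellRole.FCP_CONTROL)
        for r in range(1, 8):
            wells[well_id(r, 23)] = WellAssignment(WellRole.FMCAK_CONTROL)
        for r in range(8, 16):
            wells[well_id(r, 23)] = WellAssignment(WellRole.ANTIBODY_CONTROL)
        compound_cols = range(1, 23)
        n_rows = 16
    else:
        raise ValueError(f"unknown built-in layout: {name!r}")

    slots = [well_id(r, c) for c in compound_cols for r in range(n_rows)]
    if compound_ids is None:
        ids: list[str] = [f"cpd-{w}" for w in slots]
    else:
        if len(compound_ids) > len(slots):
            raise ValueError(
                f"{len(compound_ids)} compound ids but only {len(slots)} "
                f"compound wells on {name}"
            )
        ids = list(compound_ids)
    for w, cid in zip(slots, ids):
        wells[w] = WellAssignment(WellRole.COMPOUND, cid)
    return PlateLayout(fmt, wells)


# ---------------------------------------------------------------------------
# CSV plate maps (columns: well, role, compound_id)
# ---------------------------------------------------------------------------

def read_plate_map(path: str | Path) -> PlateLayout:
    """Read a plate map CSV with columns ``well,role,compound_id``.

    The plate format is inferred: 384 if any well lies outside the
    96-well grid (row beyond H or column beyond 12), else 96.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty plate map: {path}") from exc
    required = {"well", "role", "compound_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"plate map must have columns {sorted(required)}")
    if len(df) == 0:
        raise ValueError(f"plate map has no wells: {path}")
    wells: dict[str, WellAssignment] = {}
    coords = []
    for _, rec in df.iterrows():
        w = rec["well"].strip().upper()
        coords.append(parse_well(w))
        if w in wells:
            raise ValueError(f"duplicate well in plate map: {w}")
        wells[w] = WellAssignment(_role(rec["role"]), rec["compound_id"].strip())
    fmt = 96 if all(r < 8 and c < 12 for r, c in coords) else 384
    return PlateLayout(fmt, wells)


def write_plate_map(layout: PlateLayout, path: str | Path) -> None:
    rows = [
        {"well": w, "role": a.role.value, "compound_id": a.compound_id}
        for w, a in sorted(layout.wells.items(), key=lambda kv: parse_well(kv[0]))
    ]
    pd.DataFrame(rows, columns=["well", "role", "compound_id"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Well image series (TIFF files named <well>_<timepoint>.tif)
# ---------------------------------------------------------------------------

_IMG_RE = re.compile(r"^([A-P]\d{1,2})_(\d+)\.tiff?$", re.IGNORECASE)


def read_well_images(
    directory: str | Path,
    layout: PlateLayout | None = None,
    timepoints: tuple[int, ...] = (0, 30, 60),
    pixel_size: float = 1.0,
    bit_depth: int = 12,
) -> dict[str, dict[int, FluorescenceImage]]:
    """Read per-well TIFF time series from a directory.

    Files are named ``<well>_<minutes>.tif`` (e.g. ``A2_0.tif``).  A 2x2
    montage is treated as a single stitched field; no de-montaging is
    attempted.  Every well must have a ``t=0`` image, since polymer
    normalization is relative to the pre-enzyme baseline.
    """
    directory = Path(directory)
    series: dict[str, dict[int, FluorescenceImage]] = {}
    shape: tuple[int, int] | None = None
    for f in sorted(directory.iterdir()):
        m = _IMG_RE.match(f.name)
        if not m:
            continue
        well = m.group(1).upper()
        t = int(m.group(2))
        px = np.asarray(tifffile.imread(f), dtype=float)
        if shape is None:
            shape = px.shape  # type: ignore[assignment]
        elif px.shape != shape:
            raise ValueError(
                f"inconsistent image dimensions: {f.name} is {px.shape}, "
                f"expected {shape}"
            )
        series.setdefault(well, {})[t] = FluorescenceImage(
            px, bit_depth=bit_depth, pixel_size=pixel_size
        )
    wanted = series if layout is None else {
        w: series.get(w, {}) for w in layout.wells
        if layout.wells[w].role is not WellRole.BUFFER_BLANK
    }
    for well, imgs in wanted.items():
        if 0 not in imgs:
            raise ValueError(
                f"missing t=0 image for well {well}: baseline normalization "
                "is impossible"
            )
        for t in timepoints:
            if t not in imgs:
                raise ValueError(f"missing t={t} image for well {well}")
    return {w: dict(sorted(v.items())) for w, v in wanted.items()}


def write_well_images(
    images: dict[str, dict[int, FluorescenceImage]], directory: str | Path
) -> None:
    """Write per-well image series as 16-bit TIFFs named ``<well>_<t>.tif``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for well, imgs in images.items():
        for t, img in imgs.items():
            tifffile.imwrite(
                directory / f"{well}_{t}.tif",
                np.round(img.pixels).astype(np.uint16),
            )


# ---------------------------------------------------------------------------
# Result tables (TSV, NaN as "NA")
# ---------------------------------------------------------------------------

def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV; missing values are serialized as NA."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable thresholds and calibrations, with assay defaults.

    ``pixel_size`` converts pixels to calibration length units; the
    screen-variant particle size band is expressed in those units squared
    while the sedimentation band is raw pixels squared.
    """

    seed: int = 0
    pixel_size: float = 0.003
    # Effective post-processing MT width: the sharpen/edge halo plus the
    # boundary-chain overestimate broaden a 6 px filament to ~12 px, so
    # the perimeter-to-length conversion subtracts twice this value.
    mt_width_px: float = 12.0
    screen_size_range: tuple[float, float] = (0.0015, 0.1)
    screen_circularity_range: tuple[float, float] = (0.0, 0.7)
    sedimentation_size_range: tuple[float, float] = (110.0, float("inf"))
    sedimentation_circularity_range: tuple[float, float] = (0.0, 0.7)
    inhibitor_pct_remaining: float = 50.0   # strictly greater -> inhibitor
    activator_pct_remaining: float = 10.0   # strictly less -> activator
    fret_change_pct: float = 15.0           # |change| >= 15 -> hit
    exclude_border_particles: bool = False

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for k, v in data.items():
            if k not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key: {k}")
            if isinstance(getattr(cls(), k), tuple):
                v = tuple(float(x) for x in v)
            kwargs[k] = v
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)


def subseed(seed: int, *keys: object) -> int:
    """Derive a reproducible child seed from a global seed and string keys.

    Used so that each simulated plate/well is independent but fully
    determined by the run seed.
    """
    h = zlib.crc32("/".join(str(k) for k in keys).encode())
    return (int(seed) * 1_000_003 + h) % (2 ** 31 - 1)
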