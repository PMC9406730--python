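"""Reading confocal stacks and sample sheets; writing result tables.

The pipeline's unit of analysis is one multi-channel confocal z-stack of a
single larval CNS hemisphere.  Stacks arrive either as one multi-channel
TIFF / OME-TIFF or as a set of single-channel TIFFs sharing a filename stem
(``<stem>_GFP.tif``, ``<stem>_mCherry.tif``, ...).  A CSV sample sheet maps
each stack to its treatment / developmental-stage / replicate labels.

Physical calibration (pixel area, z spacing) is taken from configuration,
not from TIFF resolution tags: exported microscopy TIFFs carry unreliable
tags, and the pixel-to-area conversion is an explicit analysis parameter.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "GFP",
    "MCHERRY",
    "HOECHST",
    "Calibration",
    "ChannelStack",
    "HemisphereSample",
    "read_sample_sheet",
    "read_hemisphere",
    "write_quant_table",
    "QUANT_COLUMNS",
]

GFP = "GFP"
MCHERRY = "MCHERRY"
HOECHST = "HOECHST"

REQUIRED_CHANNELS = (GFP, MCHERRY)

#: spellings accepted in file names, OME metadata and sample sheets
_CHANNEL_ALIASES = {
    GFP: ("gfp", "egfp", "green"),
    MCHERRY: ("mcherry", "m_cherry", "cherry", "red"),
    HOECHST: ("hoechst", "hoechst33342", "blue"),
}


def canonical_channel(name: str) -> str | None:
    """Map a free-form channel label to GFP / MCHERRY / HOECHST (or None)."""
    key = re.sub(r"[^a-z0-9_]", "", str(name).strip().lower())
    for canon, aliases in _CHANNEL_ALIASES.items():
        if key == canon.lower() or key in aliases:
            return canon
    return None


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of the acquisition.

    Defaults correspond to a 20x/0.8 NA objective on a 16-bit sCMOS camera
    with 0.44 um optical sections, where a 100-pixel object covers 32.5 um^2
    (pixel area 0.325 um^2).
    """

    pixel_area_um2: float = 0.325
    z_step_um: float = 0.44
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not self.pixel_area_um2 > 0:
            raise ValueError(f"pixel_area_um2 must be > 0, got {self.pixel_area_um2}")
        if not self.z_step_um > 0:
            raise ValueError(f"z_step_um must be > 0, got {self.z_step_um}")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError(f"bit_depth must be one of 8, 12, 16; got {self.bit_depth}")

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class ChannelStack:
    """One channel's 3D intensity array, indexed (z, y, x)."""

    name: str
    data: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"channel {self.name!r}: expected a 3D (z, y, x) array, "
                f"got shape {self.data.shape}"
            )
        if self.data.size == 0:
            raise ValueError(f"channel {self.name!r}: empty array")
        if np.issubdtype(self.data.dtype, np.floating):
            raise ValueError(f"channel {self.name!r}: intensities must be integer-typed")
        if self.data.min() < 0:
            raise ValueError(f"channel {self.name!r}: negative intensities")
        if int(self.data.max()) > self.calibration.max_intensity:
            raise ValueError(
                f"channel {self.name!r}: max intensity {int(self.data.max())} exceeds "
                f"{self.calibration.bit_depth}-bit range"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


@dataclass
class HemisphereSample:
    """A multi-channel hemisphere stack plus its experimental metadata."""

    sample_id: str
    stacks: dict[str, ChannelStack]
    treatment: str
    stage: str
    replicate: str

    def __post_init__(self) -> None:
        for ch in REQUIRED_CHANNELS:
            if ch not in self.stacks:
                raise ValueError(f"sample {self.sample_id!r}: required channel {ch} missing")
        shapes = {ch: s.shape for ch, s in self.stacks.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(
                f"sample {self.sample_id!r}: channel dimension mismatch: {shapes}"
            )
        if not str(self.treatment).strip():
            raise ValueError(f"sample {self.sample_id!r}: treatment missing")
        if not str(self.stage).strip():
            raise ValueError(f"sample {self.sample_id!r}: stage missing")
        self.replicate = str(self.replicate)

    @property
    def gfp(self) -> ChannelStack:
        return self.stacks[GFP]

    @property
    def mcherry(self) -> ChannelStack:
        return self.stacks[MCHERRY]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.stacks[GFP].shape


# ---------------------------------------------------------------------------
# sample sheets


SHEET_COLUMNS = ("sample_id", "path", "treatment", "stage", "replicate")


def read_sample_sheet(path: str | Path) -> list[dict]:
    """Read and validate a CSV sample sheet.

    Required columns: sample_id, path, treatment, stage, replicate.
    Optional: channel_order (``;``- or ``,``-separated channel labels giving
    the channel axis order of the stack file).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path}: missing column(s) {', '.join(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"sample sheet {path}: duplicate sample_id(s): {', '.join(dup)}")
    base = Path(path).parent
    records = []
    for _, row in df.iterrows():
        rec = {c: row[c] for c in df.columns}
        # relative stack paths resolve against the sheet's own directory
        p = Path(str(rec["path"]))
        if not p.is_absolute():
            rec["path"] = str(base / p)
        records.append(rec)
    return records


def _parse_channel_order(value: str | Sequence[str] | None) -> list[str] | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str):
        parts = re.split(r"[;,|]", value)
    else:
        parts = list(value)
    out = []
    for p in parts:
        canon = canonical_channel(p)
        if canon is None:
            raise ValueError(f"unknown channel label {p!r} in channel_order")
        out.append(canon)
    return out


# ---------------------------------------------------------------------------
# stack reading


def _ome_channel_names(tif: tifffile.TiffFile) -> list[str] | None:
    """Channel names from OME-XML metadata, or None if absent."""
    xml = tif.ome_metadata
    if not xml:
        return None
    try:
        root = ET.fromstring(xml)
    except ET.ParseError:
        return None
    names = []
    for elem in root.iter():
        if elem.tag.rsplit("}", 1)[-1] == "Channel":
            names.append(elem.get("Name") or "")
    return names or None


def _to_czyx(arr: np.ndarray, axes: str) -> np.ndarray:
    """Reorder a tifffile series array with axes string to (C, Z, Y, X)."""
    axes = axes.upper().replace("S", "C").replace("Q", "Z").replace("I", "Z")
    for ax in ("C", "Z"):
        if ax not in axes:
            arr = arr[np.newaxis]
            axes = ax + axes
    if set(axes) != {"C", "Z", "Y", "X"} or len(axes) != 4:
        raise ValueError(f"unsupported TIFF axes layout {axes!r}")
    return np.transpose(arr, [axes.index(a) for a in "CZYX"])


def _read_multichannel(
    path: Path, channel_order: list[str] | None, calibration: Calibration
) -> dict[str, ChannelStack]:
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        arr = series.asarray()
        axes = series.axes
        ome_names = _ome_channel_names(tif)
    arr = _to_czyx(np.asarray(arr), axes)
    n_channels = arr.shape[0]
    # channel identity: OME metadata wins, then the sample sheet
    names: list[str] | None = None
    if ome_names and len(ome_names) == n_channels:
        mapped = [canonical_channel(n) for n in ome_names]
        if all(m is not None for m in mapped):
            names = mapped  # type: ignore[assignment]
    if names is None:
        names = channel_order
    if names is None:
        raise ValueError(
            f"{path}: cannot identify channels — no OME channel names and no "
            "channel_order in the sample sheet"
        )
    if len(names) != n_channels:
        raise ValueError(
            f"{path}: file has {n_channels} channels but {len(names)} labels given"
        )
    return {
        name: ChannelStack(name=name, data=arr[i], calibration=calibration)
        for i, name in enumerate(names)
    }


def _per_channel_candidates(path: Path, channel: str) -> list[Path]:
    stem, suffixes = path.name, ("",)
    for suf in (".ome.tif", ".ome.tiff", ".tif", ".tiff"):
        if path.name.lower().endswith(suf):
            stem = path.name[: -len(suf)]
            suffixes = (suf,)
            break
    else:
        suffixes = (".tif", ".tiff", ".ome.tif")
    spellings = {GFP: ("GFP", "gfp"), MCHERRY: ("mCherry", "mcherry", "MCHERRY"),
                 HOECHST: ("Hoechst", "hoechst", "HOECHST")}[channel]
    return [path.parent / f"{stem}_{sp}{suf}" for sp in spellings for suf in suffixes]


def _read_per_channel(
    path: Path, channel_order: list[str] | None, calibration: Calibration
) -> dict[str, ChannelStack]:
    wanted = channel_order or list(REQUIRED_CHANNELS)
    stacks: dict[str, ChannelStack] = {}
    for ch in wanted:
        if "{channel}" in str(path):
            candidates = [Path(str(path).format(channel=sp))
                          for sp in (ch, ch.lower(), ch.capitalize(), "mCherry" if ch == MCHERRY else ch)]
        else:
            candidates = _per_channel_candidates(path, ch)
        found = next((c for c in candidates if c.exists()), None)
        if found is None:
            if ch in REQUIRED_CHANNELS:
                raise FileNotFoundError(
                    f"required channel {ch} missing: no file among "
                    f"{[str(c) for c in candidates]}"
                )
            continue
        arr = tifffile.imread(found)
        arr = np.asarray(arr)
        if arr.ndim == 2:
            arr = arr[np.newaxis]
        stacks[ch] = ChannelStack(name=ch, data=arr, calibration=calibration)
    return stacks


def read_hemisphere(
    stack_path: str | Path,
    sample_row: Mapping[str, object],
    calibration: Calibration | None = None,
) -> HemisphereSample:
    """Load one hemisphere stack described by a sample-sheet record.

    ``stack_path`` is either a multi-channel TIFF/OME-TIFF, a path template
    containing ``{channel}``, or a stem resolved to per-channel files
    ``<stem>_GFP.tif`` / ``<stem>_mCherry.tif`` (``_Hoechst`` optional).
    Channel order inside a multi-channel file comes from OME metadata when
    present, otherwise from the record's ``channel_order`` field.
    """
    calibration = calibration or Calibration()
    path = Path(stack_path)
    for key in ("sample_id", "treatment", "stage", "replicate"):
        val = sample_row.get(key)
        if val is None or (isinstance(val, float) and np.isnan(val)) or not str(val).strip():
            raise ValueError(f"sample_row: {key} missing")
    channel_order = _parse_channel_order(sample_row.get("channel_order"))

    if "{channel}" in str(path) or not path.exists():
        stacks = _read_per_channel(path, channel_order, calibration)
        if not stacks and not path.exists():
            raise FileNotFoundError(f"stack not found: {path}")
    else:
        stacks = _read_multichannel(path, channel_order, calibration)

    return HemisphereSample(
        sample_id=str(sample_row["sample_id"]),
        stacks=stacks,
        treatment=str(sample_row["treatment"]),
        stage=str(sample_row["stage"]),
        replicate=str(sample_row["replicate"]),
    )


# ---------------------------------------------------------------------------
# result tables

QUANT_COLUMNS = (
    "sample_id",
    "treatment",
    "stage",
    "replicate",
    "n_gfp_punctae",
    "n_mcherry_punctae",
    "gfp_intdens_um2",
    "mcherry_intdens_um2",
    "prop_gfp_with_mcherry",
    "prop_mcherry_with_gfp",
    "gfp_threshold",
    "mcherry_threshold",
)


def write_quant_table(rows: Sequence, path: str | Path) -> None:
    """Write per-hemisphere quantification rows as CSV (fixed column order).

    Undefined proportions (zero punctae in the denominator) serialize as
    empty cells, never as 0.
    """
    if not rows:
        raise ValueError("no results to write")
    records = []
    for r in rows:
        if hasattr(r, "to_row"):
            records.append(r.to_row())
        else:
            records.append(dict(r))
    df = pd.DataFrame.from_records(records, columns=list(QUANT_COLUMNS))
    # full-precision floats so a read-back reproduces values exactly
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
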