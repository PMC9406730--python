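"""Ground-truthed synthetic dual-reporter confocal stacks.

The generator emulates the statistical structure of a mosaic heat-shock
reporter assay in a larval CNS hemisphere: a random subset of cells
expresses the sensor (cytoplasmic GFP drawn as an annulus: outer soma disk
minus the nucleus disk), and a treatment-dependent fraction of those cells
has an active reporter (nuclear mCherry drawn as the filled nucleus disk).
A further fraction of cells carries nuclear mCherry with sensor expression
below the detection threshold (dim GFP), reproducing the situation where
reporter-positive nuclei outnumber detectable sensor-expressing cells.

Each cell is confined to a single randomly chosen z-slice, so 2D per-slice
puncta counts map one-to-one onto simulated cells.  The optics/camera model
is background + structures, Gaussian PSF blur, Poisson shot noise plus
Gaussian read noise, clipped to the camera bit depth — the standard model
for a 16-bit sCMOS detector.
"""

from __future__ import annotations

import dataclasses
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .io import GFP, MCHERRY, Calibration, ChannelStack, HemisphereSample

__all__ = [
    "SyntheticSpec",
    "CellTruth",
    "GroundTruth",
    "generate_hemisphere",
    "generate_cohort",
]

MAX_PLACEMENT_ATTEMPTS = 100_000


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic hemisphere stack.

    Geometry is in pixels of a 20x field (0.325 um^2/px): a nucleus radius
    of 6 px gives a ~113 px nucleus disk, comfortably above the 100 px
    puncta size filter; the soma outer radius of 10 px gives a ~200 px
    cytoplasmic annulus.  Foreground levels around 3000 counts over a
    100-count background give the strongly bimodal histograms this assay
    produces at 16 bits.
    """

    shape: tuple[int, int, int] = (8, 512, 512)
    n_cells: int = 200
    expressing_fraction: float = 0.6
    p_coloc: float = 0.3
    p_mcherry_only: float = 0.05
    nucleus_radius_px: int = 6
    cytoplasm_outer_radius_px: int = 10
    gfp_intensity: float = 3000.0
    mcherry_intensity: float = 3000.0
    subthreshold_gfp_fraction: float = 0.15
    background_level: float = 100.0
    psf_sigma_px: float = 2.0
    noise: str = "poisson_gaussian"   # or "none"
    read_noise_sd: float = 10.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("expressing_fraction", "p_coloc", "p_mcherry_only"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.nucleus_radius_px < self.cytoplasm_outer_radius_px:
            raise ValueError("nucleus_radius_px must be < cytoplasm_outer_radius_px")
        if self.noise not in ("poisson_gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        vmax = 2**self.bit_depth - 1
        for name in ("gfp_intensity", "mcherry_intensity", "background_level"):
            if not 0 <= getattr(self, name) <= vmax:
                raise ValueError(f"{name} outside {self.bit_depth}-bit range")

    def replace(self, **overrides) -> "SyntheticSpec":
        return dataclasses.replace(self, **overrides)


@dataclass
class CellTruth:
    """One simulated cell's placement and reporter state."""

    center: tuple[int, int, int]   # (z, y, x)
    is_gfp_expressing: bool
    is_mcherry_positive: bool


@dataclass
class GroundTruth:
    """Per-cell truth plus the derived image-level quantities."""

    cells: list[CellTruth]

    @property
    def n_gfp_cells(self) -> int:
        return sum(c.is_gfp_expressing for c in self.cells)

    @property
    def n_mcherry_cells(self) -> int:
        return sum(c.is_mcherry_positive for c in self.cells)

    @property
    def true_prop_gfp_with_mcherry(self) -> float | None:
        n = self.n_gfp_cells
        if n == 0:
            return None
        return sum(c.is_gfp_expressing and c.is_mcherry_positive for c in self.cells) / n

    @property
    def true_prop_mcherry_with_gfp(self) -> float | None:
        n = self.n_mcherry_cells
        if n == 0:
            return None
        return sum(c.is_mcherry_positive and c.is_gfp_expressing for c in self.cells) / n


def _place_cells(spec: SyntheticSpec, rng: np.random.Generator) -> list[tuple[int, int, int]]:
    """Rejection-sample non-overlapping cell centers, one z-slice each.

    Same-slice centers are kept at least one blurred cell diameter apart so
    neither channel's blurred footprints merge.
    """
    nz, ny, nx = spec.shape
    margin = spec.cytoplasm_outer_radius_px + int(np.ceil(3 * spec.psf_sigma_px)) + 1
    min_dist = 2 * spec.cytoplasm_outer_radius_px + int(np.ceil(3 * spec.psf_sigma_px))
    if ny - 2 * margin <= 0 or nx - 2 * margin <= 0:
        raise ValueError(f"image shape {spec.shape} too small for cell radius + PSF margin")
    centers: list[tuple[int, int, int]] = []
    attempts = 0
    while len(centers) < spec.n_cells:
        attempts += 1
        if attempts > MAX_PLACEMENT_ATTEMPTS:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping cells in shape "
                f"{spec.shape} after {MAX_PLACEMENT_ATTEMPTS} attempts; reduce n_cells"
            )
        z = int(rng.integers(0, nz))
        y = int(rng.integers(margin, ny - margin))
        x = int(rng.integers(margin, nx - margin))
        ok = all(
            cz != z or (cy - y) ** 2 + (cx - x) ** 2 >= min_dist**2
            for cz, cy, cx in centers
        )
        if ok:
            centers.append((z, y, x))
    return centers


def _stamp_disk(img: np.ndarray, y: int, x: int, radius: int, level: float) -> None:
    yy, xx = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    disk = yy**2 + xx**2 <= radius**2
    sl = img[y - radius:y + radius + 1, x - radius:x + radius + 1]
    sl[disk] += level


def _stamp_annulus(
    img: np.ndarray, y: int, x: int, r_in: int, r_out: int, level: float
) -> None:
    yy, xx = np.ogrid[-r_out:r_out + 1, -r_out:r_out + 1]
    r2 = yy**2 + xx**2
    ring = (r2 <= r_out**2) & (r2 > r_in**2)
    sl = img[y - r_out:y + r_out + 1, x - r_out:x + r_out + 1]
    sl[ring] += level


def generate_hemisphere(
    spec: SyntheticSpec,
    sample_id: str = "synthetic",
    treatment: str = "DMSO",
    stage: str = "foraging",
    replicate: str | int = 1,
    calibration: Calibration | None = None,
) -> tuple[HemisphereSample, GroundTruth]:
    """Simulate one hemisphere stack; fully reproducible from ``spec.seed``."""
    calibration = calibration or Calibration(bit_depth=spec.bit_depth)
    rng = np.random.default_rng(spec.seed)
    centers = _place_cells(spec, rng)

    cells = []
    for center in centers:
        expressing = bool(rng.random() < spec.expressing_fraction)
        if expressing:
            mcherry = bool(rng.random() < spec.p_coloc)
        else:
            mcherry = bool(rng.random() < spec.p_mcherry_only)
        cells.append(CellTruth(center=center, is_gfp_expressing=expressing,
                               is_mcherry_positive=mcherry))

    nz, ny, nx = spec.shape
    gfp = np.full(spec.shape, spec.background_level, dtype=np.float64)
    mch = np.full(spec.shape, spec.background_level, dtype=np.float64)
    for cell in cells:
        z, y, x = cell.center
        gfp_level = (
            spec.gfp_intensity
            if cell.is_gfp_expressing
            else spec.gfp_intensity * spec.subthreshold_gfp_fraction
        )
        _stamp_annulus(gfp[z], y, x, spec.nucleus_radius_px,
                       spec.cytoplasm_outer_radius_px, gfp_level)
        if cell.is_mcherry_positive:
            _stamp_disk(mch[z], y, x, spec.nucleus_radius_px, spec.mcherry_intensity)

    vmax = float(2**spec.bit_depth - 1)
    stacks = {}
    for name, img in ((GFP, gfp), (MCHERRY, mch)):
        if spec.psf_sigma_px > 0:
            for z in range(nz):  # per-slice blur keeps cells confined to one slice
                img[z] = gaussian_filter(img[z], spec.psf_sigma_px)
        if spec.noise == "poisson_gaussian":
            img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
            img += rng.normal(0.0, spec.read_noise_sd, size=img.shape)
        img = np.clip(np.rint(img), 0, vmax).astype(np.uint16)
        stacks[name] = ChannelStack(name=name, data=img, calibration=calibration)

    sample = HemisphereSample(
        sample_id=sample_id,
        stacks=stacks,
        treatment=treatment,
        stage=stage,
        replicate=str(replicate),
    )
    return sample, GroundTruth(cells=cells)


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortArm:
    """One design row: a treatment/stage condition with n samples."""

    treatment: str
    stage: str
    n_samples: int
    overrides: Mapping[str, object] = field(default_factory=dict)


def _derive_seeds(master_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def generate_cohort(
    design: Sequence[CohortArm | tuple | Mapping],
    base_spec: SyntheticSpec,
    seed: int,
    outdir: str | Path,
) -> tuple[Path, Path]:
    """Write a cohort of OME-TIFFs plus sample sheet and ground-truth CSVs.

    Returns (sample_sheet_path, truth_path).  Per-sample seeds derive
    deterministically from ``seed``.
    """
    arms = []
    for row in design:
        if isinstance(row, CohortArm):
            arms.append(row)
        elif isinstance(row, Mapping):
            arms.append(CohortArm(
                treatment=str(row["treatment"]), stage=str(row["stage"]),
                n_samples=int(row["n_samples"]),
                overrides=dict(row.get("overrides", {})),
            ))
        else:
            t, s, n, *rest = row
            arms.append(CohortArm(t, s, int(n), dict(rest[0]) if rest else {}))

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    total = sum(a.n_samples for a in arms)
    seeds = _derive_seeds(seed, total)

    sheet_rows, truth_rows = [], []
    i = 0
    for arm in arms:
        for rep in range(1, arm.n_samples + 1):
            sample_id = f"{arm.treatment}_{arm.stage}_{rep:02d}"
            overrides = dict(arm.overrides)
            if "shape" in overrides:
                overrides["shape"] = tuple(overrides["shape"])
            spec = base_spec.replace(seed=seeds[i], **overrides)
            sample, truth = generate_hemisphere(
                spec, sample_id=sample_id, treatment=arm.treatment,
                stage=arm.stage, replicate=rep,
            )
            path = outdir / f"{sample_id}.ome.tif"
            arr = np.stack([sample.gfp.data, sample.mcherry.data], axis=1)  # ZCYX
            # deterministic UUID so repeated runs are byte-identical
            file_uuid = uuid.uuid5(uuid.NAMESPACE_URL, f"punctacoloc/{sample_id}/{spec.seed}")
            tifffile.imwrite(
                path, arr, photometric="minisblack",
                metadata={
                    "axes": "ZCYX",
                    "Channel": {"Name": ["GFP", "mCherry"]},
                    "UUID": f"urn:uuid:{file_uuid}",
                },
            )
            sheet_rows.append({
                "sample_id": sample_id, "path": path.name,
                "treatment": arm.treatment, "stage": arm.stage, "replicate": rep,
                "channel_order": "GFP;MCHERRY",
            })
            truth_rows.append({
                "sample_id": sample_id, "treatment": arm.treatment, "stage": arm.stage,
                "replicate": rep, "seed": spec.seed,
                "n_cells": len(truth.cells),
                "n_gfp_cells": truth.n_gfp_cells,
                "n_mcherry_cells": truth.n_mcherry_cells,
                "true_prop_gfp_with_mcherry": truth.true_prop_gfp_with_mcherry,
                "true_prop_mcherry_with_gfp": truth.true_prop_mcherry_with_gfp,
            })
            i += 1

    sheet_path = outdir / "samples.csv"
    truth_path = outdir / "truth.csv"
    pd.DataFrame(sheet_rows).to_csv(sheet_path, index=False)
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False)
    return sheet_path, truth_path
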