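"""Per-hemisphere quantification: counts, integrated density, colocalization.

The colocalization measure is object-based: every puncta of one channel is
measured in the other channel (on its own z-slice), classified positive or
negative, and the hemisphere-level statistic is the proportion of positive
punctae.  The proportion of GFP punctae containing an mCherry nucleus
reports the fraction of sensor-expressing cells in which the sensor drove
transcription; the reverse proportion reports how many reporter-positive
nuclei sit in cells with detectable sensor expression.  This is not the
classical intensity-weighted Manders M1/M2.

Integrated density is mean puncta fluorescence times total puncta area in
um^2, which equals (pixel area) x (sum of intensities over all puncta
pixels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .io import GFP, MCHERRY, Calibration, ChannelStack, HemisphereSample
from .segmentation import (
    DEFAULT_MIN_AREA_PX,
    PunctaSet,
    ThresholdSpec,
    segment_punctae,
    threshold_channel,
)

__all__ = [
    "CrossChannelMeasure",
    "HemisphereQuant",
    "QuantConfig",
    "measure_cross_channel",
    "overlap_proportion",
    "integrated_density",
    "quantify_hemisphere",
]


@dataclass
class CrossChannelMeasure:
    """One puncta measured in the other channel on its own slice."""

    puncta_id: str
    mean_other: float
    frac_other_positive: float
    is_positive: bool


@dataclass
class HemisphereQuant:
    """The per-hemisphere summary row.

    Overlap proportions are ``None`` (undefined, serialized as an empty
    cell) when the corresponding puncta count is zero; 0/0 is never
    reported as 0.
    """

    sample_id: str
    treatment: str
    stage: str
    replicate: str
    n_gfp_punctae: int
    n_mcherry_punctae: int
    gfp_integrated_density: float
    mcherry_integrated_density: float
    prop_gfp_with_mcherry: float | None
    prop_mcherry_with_gfp: float | None
    gfp_threshold: float
    mcherry_threshold: float

    def to_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "treatment": self.treatment,
            "stage": self.stage,
            "replicate": self.replicate,
            "n_gfp_punctae": self.n_gfp_punctae,
            "n_mcherry_punctae": self.n_mcherry_punctae,
            "gfp_intdens_um2": self.gfp_integrated_density,
            "mcherry_intdens_um2": self.mcherry_integrated_density,
            "prop_gfp_with_mcherry": self.prop_gfp_with_mcherry,
            "prop_mcherry_with_gfp": self.prop_mcherry_with_gfp,
            "gfp_threshold": self.gfp_threshold,
            "mcherry_threshold": self.mcherry_threshold,
        }


@dataclass(frozen=True)
class QuantConfig:
    """Everything :func:`quantify_hemisphere` needs besides the images."""

    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    min_area_px: int = DEFAULT_MIN_AREA_PX
    connectivity: int = 8
    tau_overlap: float = 0.1
    positivity_rule: Literal["mask_overlap", "mean_above_threshold"] = "mask_overlap"

    def __post_init__(self) -> None:
        if not 0 < self.tau_overlap <= 1:
            raise ValueError(f"tau_overlap must be in (0, 1], got {self.tau_overlap}")
        if self.positivity_rule not in ("mask_overlap", "mean_above_threshold"):
            raise ValueError(f"unknown positivity_rule {self.positivity_rule!r}")


def measure_cross_channel(
    pset: PunctaSet,
    other_stack: ChannelStack,
    other_mask: np.ndarray,
    tau_overlap: float = 0.1,
    positivity_rule: str = "mask_overlap",
    other_threshold: float | None = None,
) -> list[CrossChannelMeasure]:
    """Measure each puncta's pixels in the other channel (same z-slice).

    ``mask_overlap`` (default): positive when at least ``tau_overlap`` of
    the puncta's pixels lie inside the other channel's thresholded mask.
    ``mean_above_threshold``: positive when the puncta's mean intensity in
    the other channel exceeds that channel's threshold level.
    """
    other_mask = np.asarray(other_mask, dtype=bool)
    if other_mask.shape != other_stack.data.shape:
        raise ValueError(
            f"mask shape {other_mask.shape} != stack shape {other_stack.data.shape}"
        )
    if pset.mask.shape != other_mask.shape:
        raise ValueError(
            f"puncta-set mask shape {pset.mask.shape} != other mask {other_mask.shape}"
        )
    if not 0 < tau_overlap <= 1:
        raise ValueError(f"tau_overlap must be in (0, 1], got {tau_overlap}")
    if positivity_rule == "mean_above_threshold" and other_threshold is None:
        raise ValueError("mean_above_threshold rule requires other_threshold")

    out = []
    for p in pset.punctae:
        ys, xs = p.pixels[:, 0], p.pixels[:, 1]
        vals = other_stack.data[p.z_index][ys, xs].astype(np.float64)
        inside = other_mask[p.z_index][ys, xs]
        mean_other = float(vals.mean())
        frac = float(inside.mean())
        if positivity_rule == "mask_overlap":
            positive = frac >= tau_overlap
        else:
            positive = mean_other > float(other_threshold)  # type: ignore[arg-type]
        out.append(
            CrossChannelMeasure(
                puncta_id=p.puncta_id,
                mean_other=mean_other,
                frac_other_positive=frac,
                is_positive=positive,
            )
        )
    return out


def overlap_proportion(measures: Sequence[CrossChannelMeasure]) -> float | None:
    """Fraction of punctae classified positive; None when there are none."""
    if not measures:
        return None
    return sum(m.is_positive for m in measures) / len(measures)


def integrated_density(pset: PunctaSet, calibration: Calibration) -> float:
    """pixel_area_um2 x sum of intensities over all puncta pixels.

    Algebraically identical to (mean intensity over all puncta pixels) x
    (total puncta area in um^2).  Zero when there are no punctae.
    """
    total = sum(p.sum_intensity for p in pset.punctae)
    return calibration.pixel_area_um2 * total


def quantify_hemisphere(
    sample: HemisphereSample, config: QuantConfig | None = None
) -> HemisphereQuant:
    """Threshold, segment, cross-measure both directions; assemble the row."""
    config = config or QuantConfig()
    try:
        gfp, mch = sample.gfp, sample.mcherry
        gfp_mask, gfp_level = threshold_channel(gfp, config.threshold)
        mch_mask, mch_level = threshold_channel(mch, config.threshold)
        gfp_set = segment_punctae(
            gfp_mask, gfp, config.min_area_px, config.connectivity,
            threshold_used=gfp_level, sample_id=sample.sample_id,
        )
        mch_set = segment_punctae(
            mch_mask, mch, config.min_area_px, config.connectivity,
            threshold_used=mch_level, sample_id=sample.sample_id,
        )
        gfp_measures = measure_cross_channel(
            gfp_set, mch, mch_mask, config.tau_overlap, config.positivity_rule,
            other_threshold=mch_set.threshold_scalar,
        )
        mch_measures = measure_cross_channel(
            mch_set, gfp, gfp_mask, config.tau_overlap, config.positivity_rule,
            other_threshold=gfp_set.threshold_scalar,
        )
        cal = gfp.calibration
        return HemisphereQuant(
            sample_id=sample.sample_id,
            treatment=sample.treatment,
            stage=sample.stage,
            replicate=sample.replicate,
            n_gfp_punctae=len(gfp_set),
            n_mcherry_punctae=len(mch_set),
            gfp_integrated_density=integrated_density(gfp_set, cal),
            mcherry_integrated_density=integrated_density(mch_set, cal),
            prop_gfp_with_mcherry=overlap_proportion(gfp_measures),
            prop_mcherry_with_gfp=overlap_proportion(mch_measures),
            gfp_threshold=gfp_set.threshold_scalar,
            mcherry_threshold=mch_set.threshold_scalar,
        )
    except Exception as exc:
        try:
            wrapped = type(exc)(f"sample {sample.sample_id!r}: {exc}")
        except Exception:
            wrapped = RuntimeError(f"sample {sample.sample_id!r}: {exc}")
        raise wrapped from exc
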