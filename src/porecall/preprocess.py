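"""Percentile-based per-read signal scaling.

Pore current levels drift between reads (gain and offset vary per pore and
over time), so raw event features are not comparable across reads or to a
pore model.  Scaling fixes that with a per-read affine map chosen so the
25th/75th percentiles of event means and the median of event stdevs hit
predefined targets.  Targets default to the same statistics of the pore
model's expected levels, which makes scaled signal directly comparable to
expected signal — the property the event-to-reference alignment relies on.

Convention: means transform as ``(mean + shift) * scale`` and stdevs as
``stdev * scale_sd``; percentiles use linear interpolation between order
statistics (numpy's default).  No time-linear drift term is fitted — it is
a second-order effect at read scale; a config flag is reserved for it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import EventSequence, PoreModel, ValidationError


class DegenerateReadError(ValidationError):
    """Read statistics make the scaling map unidentifiable."""


@dataclass(frozen=True)
class ScalingParams:
    shift: float
    scale: float
    scale_sd: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shift) and np.isfinite(self.scale)
                and np.isfinite(self.scale_sd)):
            raise ValidationError("scaling parameters must be finite")
        if self.scale <= 0 or self.scale_sd <= 0:
            raise ValidationError("scale and scale_sd must be > 0")

    @classmethod
    def identity(cls) -> "ScalingParams":
        return cls(shift=0.0, scale=1.0, scale_sd=1.0)


@dataclass(frozen=True)
class ScalingTargets:
    q25_target: float
    q75_target: float
    sd_median_target: float

    def __post_init__(self) -> None:
        if not self.q25_target < self.q75_target:
            raise ValidationError("q25_target must be < q75_target")
        if self.sd_median_target <= 0:
            raise ValidationError("sd_median_target must be > 0")


def default_targets(model: PoreModel) -> ScalingTargets:
    """Targets tied to the pore model: its level-mean quartiles and
    level-stdev median."""
    q25, q75 = np.percentile(model.level_mean, [25, 75])
    return ScalingTargets(q25_target=float(q25), q75_target=float(q75),
                          sd_median_target=float(np.median(model.level_stdev)))


def compute_scaling(events: EventSequence,
                    targets: ScalingTargets) -> ScalingParams:
    """Solve for the affine map taking this read's percentiles to targets.

    After ``apply_scaling`` the scaled means' 25th/75th percentiles equal
    ``q25_target``/``q75_target`` and the scaled stdevs' median equals
    ``sd_median_target`` (exactly, up to float rounding).
    """
    if len(events) < 4:
        raise ValidationError("need at least 4 events to estimate scaling")
    q25, q75 = np.percentile(events.mean, [25, 75])
    if q75 - q25 <= 0:
        raise DegenerateReadError(
            "zero interquartile range of event means; cannot scale")
    sd_med = float(np.median(events.stdev))
    if sd_med <= 0:
        raise DegenerateReadError("zero median event stdev; cannot scale")
    scale = (targets.q75_target - targets.q25_target) / (q75 - q25)
    shift = targets.q25_target / scale - q25
    scale_sd = targets.sd_median_target / sd_med
    return ScalingParams(shift=float(shift), scale=float(scale),
                         scale_sd=float(scale_sd))


def apply_scaling(events: EventSequence, params: ScalingParams) -> EventSequence:
    """Pure transform: ``mean' = (mean + shift) * scale``,
    ``stdev' = stdev * scale_sd``; durations untouched."""
    return events.replace(mean=(events.mean + params.shift) * params.scale,
                          stdev=events.stdev * params.scale_sd)


def scale_to_model(events: EventSequence, model: PoreModel) -> EventSequence:
    """Convenience: scale a read against a pore model's default targets."""
    return apply_scaling(events, compute_scaling(events, default_targets(model)))
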