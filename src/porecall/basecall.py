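"""End-to-end 1D and 2D base-calling pipelines.

A call runs: per-read percentile scaling → feature normalisation → network
forward pass → greedy decode.  2D calling first runs both strands' 1D
networks, pairs their events by dynamic programming over the output
distributions, converts each pair column to a joint 8-wide input vector
(template features, complement features, and two presence flags), and runs
the 2D network on that sequence.  A strand missing from a 2D call degrades
to the other strand's 1D call.

Feature normalisation is a fixed affine map derived from the pore model
(not trained): event means are centred on the model's median level and
divided by its interquartile range, stdevs are centred/scaled by the median
level spread, durations pass through raw (they are already order 0.01–0.1
seconds).  The constants travel inside the model container so a saved
model is self-contained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dp_align import PairAlignment, align_event_pairs, orient_complement
from .io_model import (EventSequence, PoreModel, ValidationError,
                       load_model, save_model)
from .network import NetworkParams, OutputDistributions, decode, forward
from .preprocess import scale_to_model
from .simulate import reverse_complement

logger = logging.getLogger(__name__)

JOINT_WIDTH = 8  # t(mean, sd, dur), c(mean, sd, dur), t_flag, c_flag
ABSENT_SENTINEL = 0.0


@dataclass(frozen=True)
class FeatureNorm:
    """Fixed affine featurisation: ``x = (raw - center) / scale``."""

    center: tuple[float, float, float]
    scale: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scale):
            raise ValidationError("feature scales must be > 0")


def feature_norm(model: PoreModel) -> FeatureNorm:
    q25, q50, q75 = np.percentile(model.level_mean, [25, 50, 75])
    sd_med = float(np.median(model.level_stdev))
    return FeatureNorm(center=(float(q50), sd_med, 0.0),
                       scale=(float(q75 - q25), sd_med, 1.0))


def featurize(scaled_events: EventSequence, norm: FeatureNorm) -> np.ndarray:
    """Per-event (n, 3) network inputs from scaled events."""
    raw = np.stack([scaled_events.mean, scaled_events.stdev,
                    scaled_events.duration], axis=1)
    return (raw - np.asarray(norm.center)) / np.asarray(norm.scale)


@dataclass
class ModelBundle:
    """A trained network plus the featurisation it was trained with."""

    params: NetworkParams
    norm: FeatureNorm
    role: str = "1d"  # template_1d | complement_1d | 2d

    def save(self, path) -> None:
        save_model(self.params, path,
                   extra={"feature_center": list(self.norm.center),
                          "feature_scale": list(self.norm.scale),
                          "role": self.role})

    @classmethod
    def load(cls, path) -> "ModelBundle":
        params, extra = load_model(path)
        norm = FeatureNorm(center=tuple(extra["feature_center"]),
                           scale=tuple(extra["feature_scale"]))
        return cls(params=params, norm=norm, role=extra.get("role", "1d"))


@dataclass
class Basecall:
    read_id: str
    sequence: str
    dists: OutputDistributions
    provenance: dict = field(default_factory=dict)


def call_1d(events: EventSequence, bundle: ModelBundle,
            pore_model: PoreModel) -> Basecall:
    """Base call one strand's events with its strand-specific network."""
    if bundle.params.input_size != 3:
        raise ValidationError(
            f"1D call needs an input-width-3 network, got "
            f"{bundle.params.input_size}")
    scaled = scale_to_model(events, pore_model)
    dists = forward(bundle.params, featurize(scaled, bundle.norm))
    return Basecall(read_id=events.read_id, sequence=decode(dists),
                    dists=dists,
                    provenance={"mode": "1d", "strand": events.strand,
                                "role": bundle.role})


def build_2d_inputs(pair_alignment: PairAlignment, template_feats: np.ndarray,
                    complement_feats_oriented: np.ndarray) -> np.ndarray:
    """Joint (n_columns, 8) inputs from a pair alignment.

    ``complement_feats_oriented`` must be in template orientation (reversed
    event order); pair-alignment complement indices refer to that order.
    An absent strand contributes sentinel-zero features and a zero flag.
    """
    cols = pair_alignment.columns
    out = np.full((len(cols), JOINT_WIDTH), ABSENT_SENTINEL)
    for row, (t, c) in enumerate(cols):
        if t is not None:
            if not 0 <= t < len(template_feats):
                raise ValidationError(f"template index {t} out of range")
            out[row, 0:3] = template_feats[t]
            out[row, 6] = 1.0
        if c is not None:
            if not 0 <= c < len(complement_feats_oriented):
                raise ValidationError(f"complement index {c} out of range")
            out[row, 3:6] = complement_feats_oriented[c]
            out[row, 7] = 1.0
    return out


def call_2d(template_events: EventSequence | None,
            complement_events: EventSequence | None,
            bundles: tuple[ModelBundle, ModelBundle, ModelBundle],
            pore_model: PoreModel) -> Basecall:
    """2D call: 1D forwards on both strands, event pairing, joint network.

    ``bundles`` is (template 1D, complement 1D, 2D).  With one strand
    missing the call degrades to the available strand's 1D call (oriented
    to the template strand).
    """
    t_bundle, c_bundle, bundle_2d = bundles
    if template_events is None and complement_events is None:
        raise ValidationError("2D call requires at least one strand")
    if complement_events is None:
        logger.info("complement strand absent; falling back to template 1D")
        bc = call_1d(template_events, t_bundle, pore_model)
        bc.provenance["mode"] = "2d-fallback"
        return bc
    if template_events is None:
        logger.info("template strand absent; falling back to complement 1D")
        bc = call_1d(complement_events, c_bundle, pore_model)
        bc.sequence = reverse_complement(bc.sequence)
        bc.provenance["mode"] = "2d-fallback"
        return bc
    if bundle_2d.params.input_size != JOINT_WIDTH:
        raise ValidationError("2D network must have input width 8")
    t_scaled = scale_to_model(template_events, pore_model)
    c_scaled = scale_to_model(complement_events, pore_model)
    t_feats = featurize(t_scaled, t_bundle.norm)
    c_feats = featurize(c_scaled, c_bundle.norm)
    t_dists = forward(t_bundle.params, t_feats)
    c_dists = forward(c_bundle.params, c_feats)
    pair = align_event_pairs(t_dists, orient_complement(c_dists))
    joint = build_2d_inputs(pair, t_feats, c_feats[::-1])
    dists = forward(bundle_2d.params, joint)
    return Basecall(read_id=template_events.read_id, sequence=decode(dists),
                    dists=dists,
                    provenance={"mode": "2d", "n_columns": len(pair.columns)})
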