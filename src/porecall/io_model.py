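"""Readers and writers for event tables, FASTA references, pore models and
trained network parameter files.

Nanopore event streams have no standard on-disk format, so this package
defines small text formats of its own:

* **Event TSV** — columns ``read_id, strand, index, mean, stdev, duration``
  (header mandatory, floats rendered with 6 decimal places).  One row per
  event; the ``index`` column orders events within a read.
* **Pore-model TSV** — columns ``kmer, level_mean, level_stdev``; exactly
  ``4**k`` rows in lexicographic k-mer order.
* **Model container** — a single JSON document holding a manifest (format
  version, layer dims) plus every parameter tensor as nested lists.  JSON
  float serialisation uses Python's shortest-repr, so float64 values
  round-trip bit exactly and the file stays diffable.

FASTA is read and written through Biopython.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
ALPHABET = "ACGT-"  # dual-softmax output alphabet; '-' means "no base"

TEMPLATE = "template"
COMPLEMENT = "complement"
STRANDS = (TEMPLATE, COMPLEMENT)

_FLOAT_FMT = "%.6f"

MODEL_FORMAT_VERSION = 1


class FormatError(ValueError):
    """Raised when an on-disk file violates its declared format."""


class ValidationError(ValueError):
    """Raised when in-memory data violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Event:
    """A single segmented pore event: current mean, spread and dwell time."""

    mean: float
    stdev: float
    duration: float

    def __post_init__(self) -> None:
        for name in ("mean", "stdev", "duration"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"event {name} must be finite, got {v!r}")
        if self.stdev < 0:
            raise ValidationError(f"event stdev must be >= 0, got {self.stdev}")
        if self.duration <= 0:
            raise ValidationError(f"event duration must be > 0, got {self.duration}")


@dataclass
class EventSequence:
    """Ordered events of one read strand, stored as parallel float arrays.

    ``truth``, present only on simulated reads, holds one label string of
    0–2 bases per event (the bases the event accounts for).
    """

    read_id: str
    strand: str
    mean: np.ndarray
    stdev: np.ndarray
    duration: np.ndarray
    truth: list[str] | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.stdev = np.asarray(self.stdev, dtype=np.float64)
        self.duration = np.asarray(self.duration, dtype=np.float64)
        if self.strand not in STRANDS:
            raise ValidationError(f"unknown strand {self.strand!r}")
        n = len(self.mean)
        if n == 0:
            raise ValidationError("event sequence must be non-empty")
        if len(self.stdev) != n or len(self.duration) != n:
            raise ValidationError("mean/stdev/duration lengths differ")
        if not (np.isfinite(self.mean).all() and np.isfinite(self.stdev).all()
                and np.isfinite(self.duration).all()):
            raise ValidationError("event fields must be finite")
        if (self.stdev < 0).any():
            raise ValidationError("event stdev must be >= 0")
        if (self.duration <= 0).any():
            raise ValidationError("event duration must be > 0")
        if self.truth is not None and len(self.truth) != n:
            raise ValidationError("truth labels must have one entry per event")

    def __len__(self) -> int:
        return len(self.mean)

    @property
    def events(self) -> list[Event]:
        return [Event(m, s, d) for m, s, d in
                zip(self.mean, self.stdev, self.duration)]

    def truth_sequence(self) -> str:
        """Concatenation of per-event truth labels in traversal order."""
        if self.truth is None:
            raise ValidationError("sequence carries no truth labels")
        return "".join(self.truth)

    def replace(self, **kw) -> "EventSequence":
        data = dict(read_id=self.read_id, strand=self.strand, mean=self.mean,
                    stdev=self.stdev, duration=self.duration, truth=self.truth)
        data.update(kw)
        return EventSequence(**data)


def all_kmers(k: int) -> list[str]:
    """All 4**k k-mers over ACGT in lexicographic order."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    kmers = [""]
    for _ in range(k):
        kmers = [p + b for p in kmers for b in BASES]
    return kmers


def kmer_index(kmer: str) -> int:
    """Lexicographic rank of a k-mer (A=0, C=1, G=2, T=3 per position)."""
    idx = 0
    for b in kmer:
        idx = idx * 4 + BASES.index(b)
    return idx


@dataclass
class PoreModel:
    """Expected current mean/stdev for every k-mer context in the pore.

    ``level_mean`` and ``level_stdev`` are float arrays of length ``4**k``
    indexed lexicographically (see :func:`kmer_index`).
    """

    k: int
    level_mean: np.ndarray
    level_stdev: np.ndarray

    def __post_init__(self) -> None:
        self.level_mean = np.asarray(self.level_mean, dtype=np.float64)
        self.level_stdev = np.asarray(self.level_stdev, dtype=np.float64)
        if self.k < 1:
            raise ValidationError("pore model k must be >= 1")
        n = 4 ** self.k
        if len(self.level_mean) != n or len(self.level_stdev) != n:
            raise ValidationError(
                f"pore model must have exactly {n} entries for k={self.k}")
        if (self.level_stdev <= 0).any():
            raise ValidationError("pore model expected stdevs must be > 0")

    def level(self, kmer: str) -> tuple[float, float]:
        i = kmer_index(kmer)
        return float(self.level_mean[i]), float(self.level_stdev[i])

    def expected_means(self, sequence: str) -> np.ndarray:
        """Expected signal means for every k-mer window of ``sequence``."""
        if len(sequence) < self.k:
            raise ValidationError("sequence shorter than pore-model k")
        idx = np.array([kmer_index(sequence[i:i + self.k])
                        for i in range(len(sequence) - self.k + 1)])
        return self.level_mean[idx]


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["read_id", "strand", "index", "mean", "stdev", "duration"]


def read_event_table(path) -> list[EventSequence]:
    """Read an event TSV into one :class:`EventSequence` per (read, strand).

    Groups appear in file order; events keep their row order within a group.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "strand": str})
    except Exception as exc:  # pandas raises various parser errors
        raise FormatError(f"cannot parse event table {path}: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"event table {path} missing columns {missing}")
    for col in ("mean", "stdev", "duration"):
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise FormatError(
                f"event table {path}: non-numeric {col} at line {bad[0] + 2}")
    out: list[EventSequence] = []
    for (rid, strand), grp in df.groupby(["read_id", "strand"], sort=False):
        grp = grp.sort_values("index", kind="stable")
        try:
            out.append(EventSequence(
                read_id=str(rid), strand=str(strand),
                mean=grp["mean"].to_numpy(float),
                stdev=grp["stdev"].to_numpy(float),
                duration=grp["duration"].to_numpy(float)))
        except ValidationError as exc:
            raise ValidationError(f"read {rid} ({strand}): {exc}") from exc
    return out


def write_event_table(seqs: Iterable[EventSequence], path) -> None:
    """Write sequences as event TSV, re-readable by :func:`read_event_table`."""
    frames = []
    for s in seqs:
        frames.append(pd.DataFrame({
            "read_id": s.read_id, "strand": s.strand,
            "index": np.arange(len(s)),
            "mean": s.mean, "stdev": s.stdev, "duration": s.duration}))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=EVENT_COLUMNS))
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# pore-model tables
# ---------------------------------------------------------------------------

def read_pore_model(path) -> PoreModel:
    df = pd.read_csv(path, sep="\t", dtype={"kmer": str})
    for col in ("kmer", "level_mean", "level_stdev"):
        if col not in df.columns:
            raise FormatError(f"pore model {path} missing column {col!r}")
    k = len(df["kmer"].iloc[0])
    n = 4 ** k
    if len(df) != n:
        raise FormatError(f"pore model {path}: expected {n} rows for k={k}, "
                          f"got {len(df)}")
    mean = np.empty(n)
    stdev = np.empty(n)
    for kmer, m, s in zip(df["kmer"], df["level_mean"], df["level_stdev"]):
        i = kmer_index(kmer)
        mean[i], stdev[i] = m, s
    return PoreModel(k=k, level_mean=mean, level_stdev=stdev)


def write_pore_model(model: PoreModel, path) -> None:
    df = pd.DataFrame({"kmer": all_kmers(model.k),
                       "level_mean": model.level_mean,
                       "level_stdev": model.level_stdev})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, on_other: str = "error") -> dict[str, str]:
    """Read FASTA into an ordered name → uppercase-ACGT sequence map.

    ``on_other`` controls letters outside ACGT after uppercasing:
    ``"error"`` rejects the record, ``"mask"`` replaces them with ``A``.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"FASTA record {rec.id!r} in {path} is empty")
        if any(c not in BASES for c in seq):
            if on_other == "mask":
                seq = "".join(c if c in BASES else "A" for c in seq)
            else:
                raise FormatError(
                    f"FASTA record {rec.id!r} contains non-ACGT letters")
        out[rec.id] = seq
    return out


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

def save_model(params, path, extra: Mapping | None = None) -> None:
    """Serialise :class:`~porecall.network.NetworkParams` to a JSON container.

    ``extra`` may carry additional JSON-serialisable metadata (e.g. the
    feature-normalisation constants used by the base-calling pipeline).
    """
    from .network import NetworkParams  # local import avoids cycle

    if not isinstance(params, NetworkParams):
        raise TypeError("save_model expects NetworkParams")
    doc = {
        "format": "porecall-model",
        "version": MODEL_FORMAT_VERSION,
        "input_size": params.input_size,
        "hidden_sizes": list(params.hidden_sizes),
        "arrays": {name: arr.tolist() for name, arr in params.named_arrays()},
        "extra": dict(extra or {}),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def load_model(path):
    """Load a model container; returns ``(NetworkParams, extra_dict)``."""
    from .network import NetworkParams

    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"model file {path} is not valid JSON") from exc
    if doc.get("format") != "porecall-model":
        raise FormatError(f"{path} is not a porecall model container")
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise FormatError(f"unsupported model format version {doc.get('version')}")
    params = NetworkParams.zeros(doc["input_size"],
                                 [int(h) for h in doc["hidden_sizes"]])
    for name, expected in params.named_arrays():
        if name not in doc["arrays"]:
            raise FormatError(f"model file missing array {name!r}")
        arr = np.asarray(doc["arrays"][name], dtype=np.float64)
        if arr.shape != expected.shape:
            raise FormatError(
                f"array {name!r} has shape {arr.shape}, manifest declares "
                f"{expected.shape}")
        expected[...] = arr
    return params, doc.get("extra", {})
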