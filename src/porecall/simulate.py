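"""Synthetic nanopore data: pore models and simulated event streams.

The simulator emulates the signal process of a nanopore device at the
*event* level (segmentation of the raw current is assumed done upstream).
A DNA fragment is threaded through a k-base context window; each one-base
shift of the context ideally yields one event whose current mean/stdev are
the pore model's expected values for the k-mer plus Gaussian noise, and
whose duration is exponential.  Two segmentation error modes are modelled:

* **falsely split events** — with probability ``p_split`` a context emits
  two events; the second accounts for zero bases;
* **missed events** — with probability ``p_skip`` two consecutive contexts
  merge into a single event (their expected means averaged equally), which
  then accounts for two bases.

Each read additionally receives a random affine signal distortion
(``mean -> mean * scale + shift``, ``stdev -> stdev * scale``), emulating
per-pore drift that percentile scaling must undo.

Events are labelled with the base *entering* the context, so the
concatenated truth labels of a read equal ``seq[k-1:]`` where ``seq`` is the
fragment (template strand) or its reverse complement (complement strand):
the first ``k - 1`` bases only prime the context and are never called.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_model import (BASES, COMPLEMENT, TEMPLATE, EventSequence, PoreModel,
                       ValidationError, kmer_index, write_event_table,
                       write_fasta)

MAX_K = 8  # 4**8 = 65536 levels; larger tables are almost surely a mistake

_MIN_STDEV = 1e-3
_MIN_DURATION = 1e-6


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the event simulator.

    Defaults describe a moderately noisy pore: ~5% of contexts falsely
    split, ~5% missed, event-mean noise of 1 signal unit against level
    spacing of the default pore model (levels uniform on [50, 150]), and a
    per-read affine distortion of up to ±10% gain and ±15 units offset.
    ``duration_rate`` is the rate of the exponential dwell-time law
    (1/rate = mean duration in seconds; 25/s is a typical event rate).
    """

    k: int = 6
    p_skip: float = 0.05
    p_split: float = 0.05
    noise_mean: float = 1.0
    noise_stdev: float = 0.3
    scale: tuple[float, float] = (0.9, 1.1)
    shift: tuple[float, float] = (-15.0, 15.0)
    duration_rate: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_skip <= 1 and 0 <= self.p_split <= 1):
            raise ValidationError("p_skip and p_split must be in [0, 1]")
        if self.p_skip + self.p_split > 1:
            raise ValidationError("p_skip + p_split must be <= 1")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.noise_mean < 0 or self.noise_stdev < 0:
            raise ValidationError("noise scales must be >= 0")
        if self.duration_rate <= 0:
            raise ValidationError("duration_rate must be > 0")

    def noiseless(self) -> "SimConfig":
        """Error-free, undistorted variant of this configuration."""
        return replace(self, p_skip=0.0, p_split=0.0, noise_mean=0.0,
                       noise_stdev=0.0, scale=(1.0, 1.0), shift=(0.0, 0.0))


@dataclass
class TruthAlignment:
    """Ground-truth event-to-sequence assignment of a simulated read.

    ``labels[i]`` is the 0–2 base string event *i* accounts for and
    ``intervals[i]`` its half-open coordinate range on the read-orientation
    sequence (the fragment for the template strand, its reverse complement
    for the complement strand).  Intervals are monotone and contiguous.
    """

    strand: str
    labels: list[str]
    intervals: list[tuple[int, int]]

    def sequence(self) -> str:
        return "".join(self.labels)


def build_pore_model(k: int, seed: int) -> PoreModel:
    """Random pore model: level means i.i.d. uniform on [50, 150] signal
    units, level stdevs uniform on [0.5, 3.0].  Deterministic per seed."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > MAX_K:
        raise ValidationError(f"k={k} exceeds table-size guard (max {MAX_K})")
    rng = np.random.default_rng(seed)
    n = 4 ** k
    return PoreModel(k=k,
                     level_mean=rng.uniform(50.0, 150.0, n),
                     level_stdev=rng.uniform(0.5, 3.0, n))


def simulate_strand(fragment: str, model: PoreModel, cfg: SimConfig,
                    strand: str = TEMPLATE,
                    rng: np.random.Generator | None = None,
                    read_id: str = "read0",
                    ) -> tuple[EventSequence, TruthAlignment]:
    """Simulate one strand's event stream for ``fragment``.

    The complement strand walks the reverse complement of the fragment (the
    device reads it after the hairpin, in the opposite physical direction).
    Split is checked before skip; a skip merges exactly two consecutive
    contexts, averaging their expected means equally.
    """
    k = cfg.k
    if model.k != k:
        raise ValidationError("pore model k does not match SimConfig k")
    if len(fragment) < k:
        raise ValidationError(
            f"fragment length {len(fragment)} shorter than k={k}")
    if strand not in (TEMPLATE, COMPLEMENT):
        raise ValidationError(f"unknown strand {strand!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    seq = fragment if strand == TEMPLATE else reverse_complement(fragment)
    idx = [kmer_index(seq[i:i + k]) for i in range(len(seq) - k + 1)]
    levels = model.level_mean[idx]
    level_sds = model.level_stdev[idx]
    n_windows = len(levels)
    scale = rng.uniform(*cfg.scale)
    shift = rng.uniform(*cfg.shift)

    means: list[float] = []
    stdevs: list[float] = []
    labels: list[str] = []
    intervals: list[tuple[int, int]] = []

    def emit(level: float, sd: float, label: str, start: int) -> None:
        m = level + (rng.normal(0.0, cfg.noise_mean) if cfg.noise_mean > 0 else 0.0)
        s = sd + (rng.normal(0.0, cfg.noise_stdev) if cfg.noise_stdev > 0 else 0.0)
        means.append(m)
        stdevs.append(max(s, _MIN_STDEV))
        labels.append(label)
        intervals.append((start, start + len(label)))

    j = 0
    while j < n_windows:
        new_base = seq[j + k - 1]
        u = rng.uniform()
        if u < cfg.p_split:
            emit(levels[j], level_sds[j], new_base, j + k - 1)
            emit(levels[j], level_sds[j], "", j + k)
            j += 1
        elif u < cfg.p_split + cfg.p_skip and j + 1 < n_windows:
            merged = 0.5 * (levels[j] + levels[j + 1])
            merged_sd = 0.5 * (level_sds[j] + level_sds[j + 1])
            emit(merged, merged_sd, seq[j + k - 1:j + k + 1], j + k - 1)
            j += 2
        else:
            emit(levels[j], level_sds[j], new_base, j + k - 1)
            j += 1

    durations = np.maximum(
        rng.exponential(1.0 / cfg.duration_rate, len(means)), _MIN_DURATION)
    mean_arr = np.asarray(means) * scale + shift
    sd_arr = np.asarray(stdevs) * scale
    events = EventSequence(read_id=read_id, strand=strand, mean=mean_arr,
                           stdev=sd_arr, duration=durations, truth=list(labels))
    return events, TruthAlignment(strand=strand, labels=labels,
                                  intervals=intervals)


def simulate_2d_read(fragment: str, model: PoreModel, cfg: SimConfig,
                     rng: np.random.Generator | None = None,
                     read_id: str = "read0"):
    """Template and complement event streams of the same fragment, with
    independent noise and independent per-read distortions."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    t_events, t_truth = simulate_strand(fragment, model, cfg, TEMPLATE,
                                        rng=rng, read_id=read_id)
    c_events, c_truth = simulate_strand(fragment, model, cfg, COMPLEMENT,
                                        rng=rng, read_id=read_id)
    return t_events, c_events, (t_truth, c_truth)


@dataclass
class SimulatedRead:
    read_id: str
    start: int  # genome interval of the fragment, 0-based half-open
    end: int
    fragment: str
    template: EventSequence
    complement: EventSequence | None
    truths: tuple


@dataclass
class SimulatedDataset:
    genome: str
    model: PoreModel
    cfg: SimConfig
    reads: list[SimulatedRead] = field(default_factory=list)


def random_genome(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, length)])


def simulate_dataset(genome_length: int, n_reads: int,
                     read_length: tuple[int, int], model: PoreModel,
                     cfg: SimConfig, seed: int | None = None,
                     paired: bool = True,
                     out_dir: str | Path | None = None) -> SimulatedDataset:
    """Random genome plus reads sampled uniformly from it.

    ``read_length`` is an inclusive (min, max) range drawn uniformly per
    read.  With ``out_dir`` set, writes ``genome.fasta``, ``events.tsv`` and
    ``truth.tsv`` (columns read_id, strand, start, end, truth_seq), all
    cross-consistent and reproducible from the seed.
    """
    if genome_length <= 0 or n_reads < 0:
        raise ValidationError("genome_length must be > 0 and n_reads >= 0")
    lo, hi = read_length
    if lo < cfg.k or lo > hi:
        raise ValidationError("read_length range must satisfy k <= lo <= hi")
    if hi > genome_length:
        raise ValidationError("read length exceeds genome length")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genome = random_genome(genome_length, rng)
    ds = SimulatedDataset(genome=genome, model=model, cfg=cfg)
    for r in range(n_reads):
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, genome_length - length + 1))
        fragment = genome[start:start + length]
        rid = f"read{r:04d}"
        if paired:
            t, c, truths = simulate_2d_read(fragment, model, cfg, rng=rng,
                                            read_id=rid)
        else:
            t, t_truth = simulate_strand(fragment, model, cfg, TEMPLATE,
                                         rng=rng, read_id=rid)
            c, truths = None, (t_truth,)
        ds.reads.append(SimulatedRead(read_id=rid, start=start,
                                      end=start + length, fragment=fragment,
                                      template=t, complement=c, truths=truths))
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta({"genome": ds.genome}, out / "genome.fasta")
    seqs = []
    rows = []
    for read in ds.reads:
        for es, truth in zip(
                filter(None, (read.template, read.complement)), read.truths):
            seqs.append(es)
            rows.append({"read_id": read.read_id, "strand": es.strand,
                         "start": read.start, "end": read.end,
                         "truth_seq": truth.sequence()})
    write_event_table(seqs, out / "events.tsv")
    pd.DataFrame(rows, columns=["read_id", "strand", "start", "end",
                                "truth_seq"]).to_csv(
        out / "truth.tsv", sep="\t", index=False)
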