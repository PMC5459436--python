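"""Accuracy and sequence-composition bias reporting.

Accuracy follows the standard read-identity convention: each call is
globally aligned to its known truth sequence and accuracy is the number of
matches divided by the alignment length.  (Synthetic reads come from known
genome intervals, so a read mapper is unnecessary — the exact global
alignment to the true interval replaces it.)

Composition bias compares k-mer frequency spectra (sliding windows,
add-one pseudocount) between the reference and the pooled calls, overall
and restricted to repetitive k-mers — homopolymers and short tandem
repeats, which nanopore base callers historically under-call.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .basecall import Basecall
from .dp_align import align_sequences
from .io_model import BASES, ValidationError, all_kmers

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    accuracies: dict[str, float]
    median_accuracy: float
    mean_accuracy: float
    gc_called: float
    gc_reference: float
    n_skipped: int = 0
    kmer_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {"median_accuracy": self.median_accuracy,
                "mean_accuracy": self.mean_accuracy,
                "gc_called": self.gc_called,
                "gc_reference": self.gc_reference,
                "n_reads": len(self.accuracies),
                "n_skipped": self.n_skipped,
                "per_read_accuracy": self.accuracies}


def gc_content(sequences: str | Iterable[str]) -> float:
    """Fraction of G+C, pooled over all sequences when several are given."""
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = total = 0
    for seq in sequences:
        gc += seq.count("G") + seq.count("C")
        total += len(seq)
    if total == 0:
        raise ValidationError("gc_content of empty input")
    return gc / total


def evaluate_reads(calls: list[Basecall] | Mapping[str, str],
                   truths: Mapping[str, str]) -> EvalReport:
    """Per-read identity of calls against truths plus pooled GC content.

    Calls without a truth entry are skipped with a warning; empty calls
    score accuracy 0 (nothing aligned).
    """
    if isinstance(calls, Mapping):
        call_map = dict(calls)
    else:
        call_map = {bc.read_id: bc.sequence for bc in calls}
    accs: dict[str, float] = {}
    skipped = 0
    for rid, seq in call_map.items():
        if rid not in truths:
            logger.warning("no truth for read %s; skipped", rid)
            skipped += 1
            continue
        if not seq:
            accs[rid] = 0.0
            continue
        _, acc = align_sequences(seq, truths[rid])
        accs[rid] = acc
    if not accs:
        raise ValidationError("no calls could be evaluated")
    values = np.array(list(accs.values()))
    kept = [rid for rid in call_map if rid in truths]
    return EvalReport(
        accuracies=accs,
        median_accuracy=float(np.median(values)),
        mean_accuracy=float(values.mean()),
        gc_called=gc_content([call_map[r] for r in kept if call_map[r]]),
        gc_reference=gc_content([truths[r] for r in kept]),
        n_skipped=skipped)


def _kmer_counts(sequences: Iterable[str], k: int) -> Counter:
    counts: Counter = Counter()
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            window = seq[i:i + k]
            if all(c in BASES for c in window):
                counts[window] += 1
    return counts


def kmer_bias(calls: Iterable[str], reference: str | Iterable[str],
              k: int = 6) -> pd.DataFrame:
    """Per-k-mer sliding-window frequencies in reference vs pooled calls.

    Frequencies are computed with an add-one pseudocount on raw counts (so
    a k-mer absent from the calls sits at the pseudocount floor rather than
    zero) and normalised to sum to one on each side.  Returns columns
    ``kmer, ref_freq, called_freq, log2_ratio, repetitive`` in lexicographic
    order; ``repetitive`` flags tandem repeats of period <= 3 (the subset
    where base callers show the strongest composition bias).
    """
    refs = [reference] if isinstance(reference, str) else list(reference)
    calls = list(calls)
    if all(len(r) < k for r in refs):
        raise ValidationError(f"reference shorter than k={k}")
    kmers = all_kmers(k)
    ref_counts = _kmer_counts(refs, k)
    call_counts = _kmer_counts(calls, k)
    ref = np.array([ref_counts[m] + 1 for m in kmers], dtype=float)
    cal = np.array([call_counts[m] + 1 for m in kmers], dtype=float)
    ref /= ref.sum()
    cal /= cal.sum()
    reps = repetitive_kmers(k)
    return pd.DataFrame({"kmer": kmers, "ref_freq": ref, "called_freq": cal,
                         "log2_ratio": np.log2(cal / ref),
                         "repetitive": [m in reps for m in kmers]})


def repetitive_kmers(k: int = 6) -> set[str]:
    """k-mers that are whole-number tandem repeats of a unit of period 1, 2
    or 3 (e.g. AAAAAA, ACACAC, ACGACG for k = 6)."""
    out: set[str] = set()
    for period in (1, 2, 3):
        if k % period != 0:
            continue
        for unit in all_kmers(period):
            out.add(unit * (k // period))
    return out
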