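"""Run-length statistics of equiconformational sequences.

A maximal run of contiguous monomers sharing one conformational state within
a frame is an equiconformational sequence.  The headline statistic converts
per-frame run counts into the fraction of analyzed monomers sitting in runs
of at least one helical turn (an α-helix has 3.6 residues per turn, so the
default threshold is runs longer than three monomers):

    F_s = (1/t) * Σ_j Σ_{i >= min_len} i * R_ij / n_monomers

where R_ij counts maximal runs of exact length i in frame j and t is the
number of analyzed frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .regions import StateTrajectory

__all__ = ["RunLengthRecord", "run_lengths", "sequence_fraction", "length_histogram"]


@dataclass
class RunLengthRecord:
    """Counts of maximal same-state runs, per frame and per exact length.

    ``counts[j, i]`` is the number of maximal runs of the target state with
    exactly ``i`` contiguous monomers in frame ``j`` (column 0 is unused).
    """

    target: str
    counts: np.ndarray       # (t, n_monomers + 1) int
    n_monomers: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != self.n_monomers + 1:
            raise ValueError("counts must be (t, n_monomers + 1)")
        if np.any(self.counts < 0):
            raise ValueError("run counts must be >= 0")
        monomers = self.monomers_per_frame()
        if np.any(monomers > self.n_monomers):
            raise ValueError("runs cover more monomers than the chain holds")

    @property
    def t(self) -> int:
        """Number of analyzed frames."""
        return self.counts.shape[0]

    def monomers_per_frame(self) -> np.ndarray:
        """Σ_i i·R_ij for each frame j (monomers in the target state)."""
        lengths = np.arange(self.counts.shape[1])
        return self.counts @ lengths


def _run_length_counts(is_target: np.ndarray) -> np.ndarray:
    """Per-row counts of maximal True-runs by exact length (vectorized).

    ``is_target`` is (t, n) boolean; returns (t, n + 1) int counts.  Runs
    truncated by the chain ends count at their actual length (the chain is
    linear: no periodic joining of the last monomer to the first).
    """
    t, n = is_target.shape
    padded = np.zeros((t, n + 2), dtype=np.int8)
    padded[:, 1:-1] = is_target
    d = np.diff(padded, axis=1)
    rows, starts = np.nonzero(d == 1)
    _, ends = np.nonzero(d == -1)
    lengths = ends - starts
    counts = np.zeros((t, n + 1), dtype=np.int64)
    np.add.at(counts, (rows, lengths), 1)
    return counts


def run_lengths(states: StateTrajectory, target: str) -> RunLengthRecord:
    """Count maximal runs of ``target`` along the chain, per frame.

    A run of length 5 contributes one count at i = 5 (no nested sub-runs).
    """
    if target not in states.alphabet:
        raise KeyError(f"target {target!r} not in alphabet {states.alphabet}")
    code = states.alphabet.index(target)
    counts = _run_length_counts(states.codes == code)
    return RunLengthRecord(target=target, counts=counts,
                           n_monomers=states.n_analyzed_monomers)


def sequence_fraction(record: RunLengthRecord, min_len: int = 4,
                      n_monomers: int | None = None) -> float:
    """Fraction of monomers in target-state runs of length >= ``min_len``.

    With ``min_len`` 1 this equals the plain state fraction; it is
    non-increasing in ``min_len``.  ``n_monomers`` defaults to the record's
    chain width (30 analyzed monomers for a 32-residue chain).
    """
    if record.t == 0:
        raise ValueError("no analyzed frames (t = 0)")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if n_monomers is None:
        n_monomers = record.n_monomers
    if n_monomers <= 0:
        raise ValueError("n_monomers must be positive")
    lengths = np.arange(record.counts.shape[1])
    weights = np.where(lengths >= min_len, lengths, 0)
    total = float((record.counts * weights).sum())
    return total / (record.t * n_monomers)


def length_histogram(record: RunLengthRecord) -> np.ndarray:
    """Mean number of runs per frame for each exact length.

    Returns an array indexed by run length (entry 0 unused, always 0);
    empty above the number of analyzed monomers by construction.
    """
    if record.t < 1:
        raise ValueError("no analyzed frames")
    return record.counts.sum(axis=0) / record.t


def write_length_histogram(record: RunLengthRecord, path: str | Path) -> None:
    """Export the mean run-length distribution as TSV (i, mean_count_per_frame)."""
    hist = length_histogram(record)
    lines = ["i\tmean_count_per_frame"]
    for i in range(1, len(hist)):
        lines.append(f"{i}\t{hist[i]:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")
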