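"""Quality and ambiguity trimming of raw reads.

The quality trimmer is the modified-Mott algorithm: each base contributes
``limit - p_err`` (``p_err = 10**(-Q/10)``) and the kept segment is the
contiguous window with the maximal score sum.  Ties are broken toward the
longer window, then the smaller start.  Afterwards each end is shortened so
that no terminal run of more than ``max_ambiguous`` consecutive ``N`` remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import QualRead


@dataclass(frozen=True)
class TrimConfig:
    limit: float = 0.05
    max_ambiguous: int = 4
    min_length: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.limit < 1:
            raise ValueError("limit must be in (0, 1)")
        if self.max_ambiguous < 0:
            raise ValueError("max_ambiguous must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass(frozen=True)
class TrimSummary:
    n_in: int
    n_kept: int
    mean_len_in: float
    mean_len_kept: float


_TIE_EPS = 1e-9


def _best_window(scores: np.ndarray) -> tuple[int, int] | None:
    """Maximal-sum contiguous window as half-open (start, end).

    Ties (within 1e-9) broken toward longer windows, then smaller start.
    ``None`` when no window has a positive sum.
    """
    prefix = np.concatenate([[0.0], np.cumsum(scores, dtype=float)])
    min_val, min_idx = 0.0, 0
    best: tuple[float, int, int, int] | None = None  # sum, length, start, end
    for e in range(1, len(prefix)):
        s = prefix[e] - min_val
        cand = (s, e - min_idx, min_idx, e)
        if (
            best is None
            or s > best[0] + _TIE_EPS
            or (abs(s - best[0]) <= _TIE_EPS
                and (cand[1], -cand[2]) > (best[1], -best[2]))
        ):
            best = cand
        if prefix[e] < min_val:  # strict: keep the earliest minimum
            min_val, min_idx = prefix[e], e
    if best is None or best[0] <= _TIE_EPS:
        return None
    return best[2], best[3]


def _strip_terminal_n(seq: str, max_ambiguous: int) -> tuple[int, int]:
    """Half-open (start, end) after removing terminal N-runs longer than
    ``max_ambiguous``."""
    start, end = 0, len(seq)
    i = start
    while i < end and seq[i] == "N":
        i += 1
    if i - start > max_ambiguous:
        start = i
    j = end
    while j > start and seq[j - 1] == "N":
        j -= 1
    if end - j > max_ambiguous:
        end = j
    return start, end


def trim_read(read: QualRead, cfg: TrimConfig = TrimConfig()) -> QualRead | None:
    """Trim one read; ``None`` means rejected (too short after trimming)."""
    if len(read) == 0:
        return None
    p_err = 10.0 ** (-np.asarray(read.quals, dtype=float) / 10.0)
    window = _best_window(cfg.limit - p_err)
    if window is None:
        return None
    start, end = window
    seq = read.seq[start:end]
    ns, ne = _strip_terminal_n(seq, cfg.max_ambiguous)
    start, end = start + ns, start + ne
    if end - start < cfg.min_length:
        return None
    return QualRead(read.id, read.seq[start:end], read.quals[start:end])


def trim_library(reads: list[QualRead],
                 cfg: TrimConfig = TrimConfig()) -> tuple[list[QualRead], TrimSummary]:
    kept = []
    for r in reads:
        t = trim_read(r, cfg)
        if t is not None:
            kept.append(t)
    mean_in = float(np.mean([len(r) for r in reads])) if reads else 0.0
    mean_kept = float(np.mean([len(r) for r in kept])) if kept else 0.0
    return kept, TrimSummary(len(reads), len(kept), mean_in, mean_kept)
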