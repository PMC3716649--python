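"""Two-point linkage placement of a biallelic marker on a doubled-haploid map.

DH lines are fully homozygous, so the recombination fraction between two
markers is estimated by direct counting over informative (both-called)
lines.  Map distances use the Kosambi function by default; significance of
linkage is a one-sided binomial test of r < 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

MISSING = "-"


class InsufficientDataError(ValueError):
    pass


@dataclass
class DHGenotypes:
    """Lines x markers calls in {A, B, -}."""

    lines: list[str]
    markers: list[str]
    calls: np.ndarray  # dtype '<U1', shape (n_lines, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U1")
        if self.calls.shape != (len(self.lines), len(self.markers)):
            raise ValueError("calls shape does not match lines x markers")
        bad = set(np.unique(self.calls)) - {"A", "B", MISSING}
        if bad:
            raise ValueError(f"genotype calls outside {{A,B,-}}: {sorted(bad)}")

    @property
    def missing_rate(self) -> float:
        return float(np.mean(self.calls == MISSING))

    def column(self, marker: str) -> np.ndarray:
        return self.calls[:, self.markers.index(marker)]

    @classmethod
    def read_csv(cls, path: str | Path) -> "DHGenotypes":
        df = pd.read_csv(path, index_col=0, dtype=str).fillna(MISSING)
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.calls, index=self.lines,
                     columns=self.markers).to_csv(path)


def kosambi(r: float) -> float:
    """Map distance in cM: d = 25 ln((1+2r)/(1-2r))."""
    if r >= 0.5:
        return math.inf
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


def haldane(r: float) -> float:
    """Map distance in cM: d = -50 ln(1-2r)."""
    if r >= 0.5:
        return math.inf
    return -50.0 * math.log(1 - 2 * r)


_MAP_FUNCTIONS = {"kosambi": kosambi, "haldane": haldane}


@dataclass(frozen=True)
class LinkageResult:
    marker_pair: tuple[str, str]
    n_informative: int
    n_recombinant: int
    r: float
    cm: float
    lod: float
    p: float
    repulsion_flag: bool  # raw recombinant fraction exceeded 0.5


def two_point(m1: str, m2: str, genotypes: DHGenotypes,
              map_function: str = "kosambi") -> LinkageResult:
    """Direct-count two-point linkage between two markers."""
    a = genotypes.column(m1)
    b = genotypes.column(m2)
    informative = (a != MISSING) & (b != MISSING)
    n = int(informative.sum())
    if n < 2:
        raise InsufficientDataError(
            f"only {n} informative lines for {m1} x {m2}")
    k = int((a[informative] != b[informative]).sum())
    raw_r = k / n
    repulsion = raw_r > 0.5
    r = min(raw_r, 0.5)
    if 0 < raw_r < 1:
        lod = (k * math.log10(raw_r / 0.5)
               + (n - k) * math.log10((1 - raw_r) / 0.5))
    else:
        lod = n * math.log10(2.0)
    lod = max(lod, 0.0)
    cm = _MAP_FUNCTIONS[map_function](r)
    p = binomtest(k, n, 0.5, alternative="less").pvalue
    return LinkageResult((m1, m2), n, k, r, cm, max(lod, 0.0), float(p),
                         repulsion)


@dataclass(frozen=True)
class Placement:
    placed: bool
    marker: str | None
    chromosome: str | None
    cm_from_marker: float | None
    result: LinkageResult | None
    alpha: float


def place_marker(new_marker: str, marker_map: pd.DataFrame,
                 genotypes: DHGenotypes, alpha: float = 0.001,
                 map_function: str = "kosambi") -> Placement:
    """Place a marker next to its most significantly linked map marker.

    ``marker_map`` needs columns ``marker``, ``chromosome``, ``cm``.
    Unplaced when no map marker is linked at ``alpha``.
    """
    best: LinkageResult | None = None
    best_row = None
    for _, row in marker_map.iterrows():
        if row["marker"] not in genotypes.markers:
            continue
        try:
            res = two_point(new_marker, row["marker"], genotypes, map_function)
        except InsufficientDataError:
            continue
        if res.p < alpha and (best is None or (res.p, res.r) < (best.p, best.r)):
            best = res
            best_row = row
    if best is None:
        return Placement(False, None, None, None, None, alpha)
    return Placement(True, best_row["marker"], str(best_row["chromosome"]),
                     best.cm, best, alpha)


# ---------------------------------------------------------------------------
# simulation helper (testing/acceptance): DH gametes by binomial recombination
# ---------------------------------------------------------------------------

def simulate_dh_genotypes(n_lines: int, map_rs: Sequence[float], seed: int,
                          markers: Sequence[str] | None = None,
                          missing_rate: float = 0.0) -> DHGenotypes:
    """A DH population over a linear marker chain with the given adjacent
    recombination fractions (len(map_rs) + 1 markers)."""
    rng = np.random.default_rng(seed)
    n_markers = len(map_rs) + 1
    if markers is None:
        markers = [f"m{i + 1}" for i in range(n_markers)]
    calls = np.empty((n_lines, n_markers), dtype="<U1")
    first = rng.random(n_lines) < 0.5
    calls[:, 0] = np.where(first, "A", "B")
    for j, r in enumerate(map_rs, start=1):
        rec = rng.random(n_lines) < r
        prev = calls[:, j - 1]
        flipped = np.where(prev == "A", "B", "A")
        calls[:, j] = np.where(rec, flipped, prev)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = MISSING
    return DHGenotypes([f"line{i + 1}" for i in range(n_lines)],
                       list(markers), calls)


def write_placement_tsv(placement: Placement, new_marker: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("marker\tplaced\tlinked_marker\tchromosome\tcM\tr\tLOD\tp\t"
                 "informative\trecombinant\n")
        if placement.placed:
            r = placement.result
            fh.write(f"{new_marker}\t1\t{placement.marker}\t"
                     f"{placement.chromosome}\t{r.cm:.2f}\t{r.r:.4f}\t"
                     f"{r.lod:.2f}\t{r.p:.3g}\t{r.n_informative}\t"
                     f"{r.n_recombinant}\n")
        else:
            fh.write(f"{new_marker}\t0\t.\t.\t.\t.\t.\t.\t.\t.\n")
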