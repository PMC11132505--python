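"""Sliding-window LCD detection and classification.

A protein is scanned with a fixed-width window (default 20 residues, unit
stride). A window belongs to an LCD class when the windowed composition of the
class's primary amino acid reaches the primary threshold (default 40%), the
secondary amino acid — for the 380 two-letter classes — reaches the secondary
threshold (default 20%), and the *linear dispersion* of each searched amino
acid within the window is at least the dispersion threshold (default 0.5).
All overlapping passing windows are merged into contiguous domains, reported
with 1-based inclusive coordinates and the composition of the merged span.

Linear dispersion measures how evenly a target residue is spread across the
window, on [0, 1] with 1 = perfectly even. For k occurrences at positions
p_1 < … < p_k in a window of width W we take the k+1 boundary-inclusive gaps
(p_1, p_2−p_1, …, W+1−p_k), whose population standard deviation σ is then
min–max normalized against the most even (σ_min) and most clustered (σ_max)
placements of k residues in a W-window:

    dispersion = 1 − (σ − σ_min) / (σ_max − σ_min)

With fewer than two occurrences, or when σ_max = σ_min (e.g. a homopolymer
window), the statistic is defined as 1. Both extremes have closed forms —
most even: gaps as equal as possible; most clustered: one gap of W−k+1 and k
gaps of 1 — and are brute-force verifiable by enumerating placements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classes import CANONICAL_AA, ClassSpec
from .errors import ConfigurationError
from .proteome import ProteinRecord, Proteome

# tolerance for >= threshold comparisons on float fractions
_EPS = 1e-9

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}

#: Columns of the long-format LCD table produced by :func:`scan_proteome`.
LCD_TABLE_COLUMNS = (
    "proteome_id", "accession", "class_label", "start", "end",
    "length", "sequence", "primary_comp", "secondary_comp",
)


@dataclass
class LCD:
    """One merged low-complexity domain (1-based inclusive coordinates)."""

    accession: str
    class_label: str
    start: int
    end: int
    sequence: str
    composition: dict[str, float]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def composition(window: str, aa: str) -> float:
    """Fraction of ``window`` positions equal to ``aa``.

    Non-canonical letters count toward the window length but toward no amino
    acid, so fractions over a window sum to at most 1.
    """
    if len(window) == 0:
        raise ValueError("composition of an empty window is undefined")
    return window.count(aa) / len(window)


def _gap_sigma(gaps: Sequence[int]) -> float:
    n = len(gaps)
    mean = sum(gaps) / n
    return math.sqrt(sum((g - mean) ** 2 for g in gaps) / n)


def _sigma_min(k: int, W: int) -> float:
    # most even placement: k+1 gaps summing to W+1, as equal as possible
    n = k + 1
    q, r = divmod(W + 1, n)
    return _gap_sigma([q + 1] * r + [q] * (n - r))


def _sigma_max(k: int, W: int) -> float:
    # most clustered placement: run of k at one end -> one gap of W-k+1, k of 1
    return _gap_sigma([W - k + 1] + [1] * k)


def dispersion_from_positions(positions: Sequence[int], window_size: int) -> float:
    """Linear dispersion for 1-based occurrence ``positions`` in a window."""
    k = len(positions)
    if k < 2:
        return 1.0
    W = window_size
    gaps = [positions[0]]
    gaps.extend(positions[i + 1] - positions[i] for i in range(k - 1))
    gaps.append(W + 1 - positions[-1])
    smin = _sigma_min(k, W)
    smax = _sigma_max(k, W)
    if smax - smin <= 1e-12:
        return 1.0
    d = 1.0 - (_gap_sigma(gaps) - smin) / (smax - smin)
    return min(1.0, max(0.0, d))


def linear_dispersion(window: str, aa: str) -> float:
    """Linear dispersion of ``aa`` within ``window`` (1 = evenly spread)."""
    if len(window) < 2:
        raise ValueError("linear dispersion needs a window of length >= 2")
    positions = [i + 1 for i, ch in enumerate(window) if ch == aa]
    return dispersion_from_positions(positions, len(window))


def _window_counts(seq: str, window_size: int) -> np.ndarray:
    """(n_windows, 20) canonical amino-acid counts for every window."""
    L = len(seq)
    W = window_size
    if L < W:
        return np.zeros((0, len(CANONICAL_AA)), dtype=np.int64)
    codes = np.fromiter((_AA_INDEX.get(ch, -1) for ch in seq), dtype=np.int64, count=L)
    onehot = np.zeros((L + 1, len(CANONICAL_AA)), dtype=np.int64)
    valid = codes >= 0
    onehot[1:][valid, codes[valid]] = 1
    cumsum = np.cumsum(onehot, axis=0)
    return cumsum[W:] - cumsum[:-W]


def _positions_in_window(all_pos: np.ndarray, start0: int, W: int) -> list[int]:
    lo = np.searchsorted(all_pos, start0)
    hi = np.searchsorted(all_pos, start0 + W)
    return [int(p - start0 + 1) for p in all_pos[lo:hi]]


def _find_passing_starts(seq: str, spec: ClassSpec,
                         counts: np.ndarray | None = None) -> list[int]:
    W = spec.window_size
    if len(seq) < W:
        return []
    if counts is None:
        counts = _window_counts(seq, W)
    pi = _AA_INDEX[spec.primary_aa]
    mask = counts[:, pi] >= spec.primary_threshold * W - _EPS
    if spec.secondary_aa is not None:
        si = _AA_INDEX[spec.secondary_aa]
        mask &= counts[:, si] >= spec.secondary_threshold * W - _EPS
    candidates = np.nonzero(mask)[0]
    if candidates.size == 0:
        return []
    delta = spec.dispersion_threshold
    prim_pos = np.array([i for i, ch in enumerate(seq) if ch == spec.primary_aa])
    sec_pos = (np.array([i for i, ch in enumerate(seq) if ch == spec.secondary_aa])
               if spec.secondary_aa is not None else None)
    starts: list[int] = []
    for s0 in candidates:
        s0 = int(s0)
        d = dispersion_from_positions(_positions_in_window(prim_pos, s0, W), W)
        if d < delta - _EPS:
            continue
        if sec_pos is not None:
            d2 = dispersion_from_positions(_positions_in_window(sec_pos, s0, W), W)
            if d2 < delta - _EPS:
                continue
        starts.append(s0 + 1)
    return starts


def find_passing_windows(sequence: str, spec: ClassSpec) -> list[int]:
    """1-based start positions of all windows satisfying ``spec``.

    A window [s, s+W−1] passes when the primary composition reaches c1, the
    secondary composition (if a secondary amino acid is set) reaches c2, and
    the linear dispersion of each searched amino acid is at least δ.
    Sequences shorter than W yield an empty list.
    """
    if not isinstance(spec, ClassSpec):
        raise ConfigurationError("spec must be a ClassSpec")
    return _find_passing_starts(sequence, spec)


def merge_windows(starts: Sequence[int], window_size: int) -> list[tuple[int, int]]:
    """Merge overlapping windows into maximal contiguous intervals.

    ``starts`` are sorted, distinct 1-based window starts; two windows merge
    when their spans share at least one residue. Returns disjoint, sorted
    (start, end) intervals, 1-based inclusive.
    """
    W = window_size
    intervals: list[tuple[int, int]] = []
    for s in starts:
        e = s + W - 1
        if intervals and s <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], e))
        else:
            intervals.append((s, e))
    return intervals


def _span_composition(span: str) -> dict[str, float]:
    L = len(span)
    return {aa: span.count(aa) / L for aa in CANONICAL_AA if aa in span}


def _scan_sequence(accession: str, seq: str, spec: ClassSpec,
                   counts: np.ndarray | None = None) -> list[LCD]:
    starts = _find_passing_starts(seq, spec, counts)
    lcds = []
    for a, b in merge_windows(starts, spec.window_size):
        span = seq[a - 1:b]
        lcds.append(LCD(accession, spec.label, a, b, span, _span_composition(span)))
    return lcds


def scan_protein(protein: ProteinRecord, spec: ClassSpec) -> list[LCD]:
    """All merged LCDs of one class in one protein.

    Merged domains are reported without re-filtering: every constituent
    window already passed the thresholds, and the merged span's composition
    may fall below them.
    """
    return _scan_sequence(protein.accession, protein.sequence, spec)


def scan_proteome(proteome: Proteome, specs: Iterable[ClassSpec]) -> pd.DataFrame:
    """Scan every protein with every class spec; long-format LCD table.

    Per-window amino-acid counts are computed once per (protein, window size)
    and shared across class predicates, which is output-identical to
    independent per-class scans.
    """
    specs = list(specs)
    rows: list[tuple] = []
    for protein in proteome.proteins:
        counts_by_w: dict[int, np.ndarray] = {}
        for spec in specs:
            W = spec.window_size
            if W not in counts_by_w:
                counts_by_w[W] = _window_counts(protein.sequence, W)
            for lcd in _scan_sequence(protein.accession, protein.sequence,
                                      spec, counts_by_w[W]):
                rows.append((
                    proteome.proteome_id, lcd.accession, lcd.class_label,
                    lcd.start, lcd.end, lcd.length, lcd.sequence,
                    lcd.composition.get(spec.primary_aa, 0.0),
                    lcd.composition.get(spec.secondary_aa, 0.0)
                    if spec.secondary_aa is not None else float("nan"),
                ))
    return pd.DataFrame(rows, columns=list(LCD_TABLE_COLUMNS))
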