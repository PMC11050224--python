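"""Raw-sequence period spectrum and initial monomer segmentation.

The repeat spectrum records, for every position, the distance to the next
exact occurrence of the k-word starting there; tandem alpha satellite produces
peaks at multiples of ~171 bp.  Regions whose local periodicity sits at the
monomer length are tiled into candidate monomers, choosing the tiling phase
that yields the fewest distinct monomer classes (phase cuts inside monomers
create spurious junction types, so the true boundary minimises the count).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "RawSpectrum",
    "TandemRegion",
    "raw_repeat_spectrum",
    "find_peaks",
    "find_tandem_regions",
    "extract_candidate_monomers",
]


@dataclass
class RawSpectrum:
    """Histogram of next-occurrence distances of exact k-words."""

    counts: dict[int, int]
    word_length: int
    max_period: int
    window: int
    seq_length: int = 0
    # per-position distance to the next occurrence of the word starting there
    # (0 where none within the window); reused by find_tandem_regions
    next_distance: np.ndarray | None = field(default=None, repr=False)

    def total(self) -> int:
        return sum(self.counts.values())

    def argmax(self) -> int | None:
        if not self.counts:
            return None
        return max(self.counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]

    def as_array(self) -> np.ndarray:
        arr = np.zeros(self.max_period + 1, dtype=np.int64)
        for p, c in self.counts.items():
            arr[p] = c
        return arr


def raw_repeat_spectrum(
    sequence: str,
    word_length: int = 12,
    max_period: int = 6000,
    window: int | None = None,
) -> RawSpectrum:
    """Distance histogram over consecutive occurrences of exact k-words.

    For each position the distance to the next occurrence of its word is
    recorded if it does not exceed ``window`` (default: ``max_period``);
    positions whose word never recurs contribute nothing.
    """
    if word_length < 8:
        raise ValueError("word_length must be >= 8")
    if window is None:
        window = max_period
    seq = sequence.upper()
    n = len(seq)
    counts: Counter[int] = Counter()
    next_dist = np.zeros(n, dtype=np.int32)
    if n >= word_length:
        last: dict[str, int] = {}
        limit = min(window, max_period)
        for i in range(n - word_length + 1):
            w = seq[i : i + word_length]
            j = last.get(w)
            if j is not None:
                d = i - j
                if d <= limit:
                    counts[d] += 1
                    next_dist[j] = d
            last[w] = i
    return RawSpectrum(dict(counts), word_length, max_period, window, n, next_dist)


def find_peaks(
    spectrum: RawSpectrum,
    min_period: int = 50,
    min_count: int = 10,
    n_mads: float = 5.0,
) -> list[int]:
    """Periods whose count stands above the noise floor.

    The threshold is ``median + n_mads * 1.4826 * MAD`` over all periods in
    ``[min_period, max_period]`` (absent periods count as zero) with a hard
    floor of ``min_count``; the robust location/scale keeps the handful of
    genuine tall peaks from inflating the cutoff.  Runs of above-threshold
    periods within 5 bp are consolidated to their summit.
    """
    arr = spectrum.as_array()[min_period:]
    if arr.size == 0:
        return []
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    thr = max(float(min_count), med + n_mads * 1.4826 * mad)
    above = np.nonzero(arr > thr)[0] + min_period
    peaks: list[int] = []
    spec = spectrum.as_array()
    for p in above:
        if peaks and p - peaks[-1] <= 5:
            if spec[p] > spec[peaks[-1]]:
                peaks[-1] = int(p)
        else:
            peaks.append(int(p))
    return peaks


@dataclass
class TandemRegion:
    """A run of tandem ~monomer-length periodicity tiled into candidates."""

    start: int
    end: int  # 0-based half-open
    base_period: int
    monomer_intervals: list[tuple[int, int]]


def _tile_classes(tiles: list[str], threshold: float) -> list[int]:
    """Greedy single-pass clustering of tiles; returns one label per tile."""
    reps: list[str] = []
    labels: list[int] = []
    for t in tiles:
        lt = len(t)
        for li, r in enumerate(reps):
            d = edlib.align(t, r, mode="NW", task="distance",
                            k=int(threshold / 100.0 * lt) + 1)["editDistance"]
            if d >= 0 and 100.0 * d / max(lt, len(r)) < threshold:
                labels.append(li)
                break
        else:
            labels.append(len(reps))
            reps.append(t)
    return labels


def _class_mismatch_score(tiles: list[str], labels: list[int]) -> int:
    """Total disagreement of tiles with their class column consensus.

    A boundary-aligned tiling leaves only mutation noise inside each class;
    a shifted tiling imports junction bases from neighbouring monomers whose
    context differs for part of a class, inflating the column disagreement.
    Exactly zero for a boundary-aligned noise-free cascading array.
    """
    total = 0
    for lab in set(labels):
        members = [t for t, l in zip(tiles, labels) if l == lab]
        if len(members) < 2:
            continue
        mat = np.vstack([np.frombuffer(m.encode(), dtype=np.uint8) for m in members])
        best = np.zeros(mat.shape[1], dtype=np.int64)
        for base in (65, 67, 71, 84):  # A C G T
            best = np.maximum(best, (mat == base).sum(axis=0))
        total += mat.shape[0] * mat.shape[1] - int(best.sum())
    return total


def _select_phase(
    region_seq: str,
    period: int,
    max_tiles: int = 60,
    class_threshold: float = 7.0,
    edge_window: int = 8,
) -> int:
    """Pick the tiling offset in ``[0, period)``.

    The region boundary itself anchors the monomer frame: periodicity
    evidence starts at the first monomer of the array, so the true boundary
    lies within a few bp of the region start.  Only offsets within
    ``edge_window`` bp of the region start (wrapping through the period) are
    considered — a frame cutting mid-monomer would manufacture spurious
    junction types.  Within the window, offsets are ranked by monomer class
    count, then by within-class column disagreement (exactly zero at the
    true boundary of a noise-free cascading array), then by distance to the
    region start.  For a phase-degenerate Willard's array every candidate
    ties and the region start wins: the frame is then genuinely
    conventional.
    """
    n_tiles = min(max_tiles, (len(region_seq) - period + 1) // period)
    if n_tiles < 2:
        return 0

    def tiles_at(off: int) -> list[str]:
        k = min(n_tiles, (len(region_seq) - off) // period)
        return [region_seq[off + i * period : off + (i + 1) * period] for i in range(k)]

    window = min(edge_window, (period - 1) // 2)
    best: tuple[int, int, int, int] | None = None
    for delta in range(-window, window + 1):
        off = delta % period
        tiles = tiles_at(off)
        if len(tiles) < 2:
            continue
        labels = _tile_classes(tiles, class_threshold)
        key = (
            len(set(labels)),
            _class_mismatch_score(tiles, labels),
            abs(delta),
            off,
        )
        if best is None or key < best:
            best = key
    return best[3] if best else 0


def find_tandem_regions(
    sequence: str,
    spectrum: RawSpectrum | None = None,
    target_period: int = 171,
    tolerance: int = 10,
    min_monomers: int = 5,
    density_threshold: float = 0.25,
    density_window: int | None = None,
    merge_gap: int = 500,
) -> list[TandemRegion]:
    """Locate maximal regions periodic at ~``target_period`` and tile them.

    A position is evidence for tandem structure when its word recurs at a
    distance within ``tolerance`` of any multiple of the target period (both
    endpoints of the match are marked, so array tails are covered).  Maximal
    runs with smoothed evidence density above ``density_threshold`` become
    regions; each region estimates its fundamental period and is tiled into
    candidate monomer intervals at the phase chosen by :func:`_select_phase`.
    """
    if spectrum is None or spectrum.next_distance is None or spectrum.seq_length != len(sequence):
        spectrum = raw_repeat_spectrum(sequence)
    nd = spectrum.next_distance
    n = len(sequence)
    if n == 0:
        return []
    pos = np.nonzero(nd > 0)[0]
    d = nd[pos].astype(np.int64)
    k = np.round(d / target_period).astype(np.int64)
    ok = (k >= 1) & (np.abs(d - k * target_period) <= tolerance)
    pos, d, k = pos[ok], d[ok], k[ok]
    evidence = np.zeros(n, dtype=bool)
    evidence[pos] = True
    evidence[np.minimum(pos + d, n - 1)] = True
    if density_window is None:
        density_window = 5 * target_period
    density = uniform_filter1d(evidence.astype(np.float32), size=density_window, mode="constant")
    mask = density >= density_threshold
    # maximal runs of the mask, trimmed to actual evidence, then merged
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    raw_runs = list(zip(edges[0::2], edges[1::2]))
    runs: list[list[int]] = []
    for s, e in raw_runs:
        ev = np.nonzero(evidence[s:e])[0]
        if ev.size == 0:
            continue
        s2, e2 = s + int(ev[0]), s + int(ev[-1]) + spectrum.word_length
        if runs and s2 - runs[-1][1] < merge_gap:
            runs[-1][1] = max(runs[-1][1], e2)
        else:
            runs.append([s2, min(e2, n)])
    regions: list[TandemRegion] = []
    for s, e in runs:
        if e - s < max(2 * target_period, min_monomers * target_period):
            continue
        sel = (pos >= s) & (pos < e)
        if not sel.any():
            continue
        fundamentals = np.round(d[sel] / k[sel]).astype(np.int64)
        base_period = int(Counter(fundamentals.tolist()).most_common(1)[0][0])
        region_seq = sequence[s:e]
        off = _select_phase(region_seq, base_period)
        intervals = []
        p = s + off
        while p + base_period <= e:
            intervals.append((p, p + base_period))
            p += base_period
        if len(intervals) < min_monomers:
            continue
        regions.append(TandemRegion(s, e, base_period, intervals))
    return regions


def extract_candidate_monomers(sequence: str, regions: list[TandemRegion]) -> list[str]:
    """One forward-strand sequence per candidate monomer interval."""
    return [sequence[s:e] for reg in regions for s, e in reg.monomer_intervals]
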