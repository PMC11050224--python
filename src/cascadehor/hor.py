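"""HOR structure inference from the enumerated monomer track.

The monomer-distance (MD) series assigns to each enumerated monomer the index
distance to the next monomer of the same family; its histogram is the
monomer-level GRM spectrum.  Dense horizontal MD lines reveal HOR arrays and
their primary period n; shorter supported periods are subfragments (e.g.
4/7/11 inside the cascading 15mer), longer ones are secondary/tertiary repeats
(the 34-monomer doublet hybrid of the 25mer array).  Canonical units are the
most frequent cyclic type subsequence of length n, copies are segmented and
classified canonical/variant, and the cascading scheme arranges each copy's
monomers into rows aligned by type columns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .scanning import MonomerTrack

__all__ = [
    "MDPoint",
    "HORArrayRegion",
    "HORCopy",
    "CascadingScheme",
    "UnitComparison",
    "md_series",
    "monomer_grm_spectrum",
    "detect_hor_arrays",
    "infer_canonical_unit",
    "segment_copies",
    "build_scheme",
    "subfragment_periods",
    "secondary_periods",
    "compare_units",
]


@dataclass(frozen=True)
class MDPoint:
    """(enumeration index, period) — the atom of the MD diagram.

    ``period`` is None for the final occurrence of a family (there is no
    subsequent monomer of the same type), mirroring the sporadic unplotted
    points of the MD diagram.
    """

    enumeration_index: int
    family_id: int
    period: int | None


def md_series(track: MonomerTrack) -> list[MDPoint]:
    """Index distance from each enumerated monomer to the next of its family."""
    mono = track.enumerated()
    points: list[MDPoint] = []
    next_seen: dict[int, int] = {}
    for m in reversed(mono):
        idx = m.enumeration_index
        nxt = next_seen.get(m.family_id)
        points.append(MDPoint(idx, m.family_id, None if nxt is None else nxt - idx))
        next_seen[m.family_id] = idx
    points.reverse()
    return points


def monomer_grm_spectrum(md_points: list[MDPoint]) -> dict[int, int]:
    """Histogram of MD periods (monomer units) — the monomer-level GRM."""
    return dict(Counter(p.period for p in md_points if p.period is not None))


@dataclass
class HORArrayRegion:
    """A contiguous enumeration span carrying one HOR structure."""

    first: int
    last: int  # inclusive enumeration span
    primary_period: int
    support: float
    subfragment_periods: set[int] = field(default_factory=set)
    secondary_periods: set[int] = field(default_factory=set)
    genomic_span: tuple[int, int] | None = None
    local_type_index: dict[int, int] = field(default_factory=dict)

    @property
    def n_monomers(self) -> int:
        return self.last - self.first + 1


def _region_points(md_points: list[MDPoint], region: HORArrayRegion) -> list[MDPoint]:
    return [p for p in md_points if region.first <= p.enumeration_index <= region.last]


def subfragment_periods(
    md_points: list[MDPoint],
    region: HORArrayRegion,
    min_copy_fraction: float = 0.5,
) -> set[int]:
    """Periods below the primary period recurring in most HOR copies.

    A period ``p < n`` qualifies when its MD count reaches
    ``min_copy_fraction`` times the estimated copy number (region monomers /
    n): a subfragment is a structural feature of the unit, so it must recur
    copy for copy, while stray variant-induced distances appear only a few
    times.
    """
    pts = _region_points(md_points, region)
    n = region.primary_period
    copies = region.n_monomers / n
    counts = Counter(p.period for p in pts if p.period is not None and p.period < n)
    return {p for p, c in counts.items() if c >= min_copy_fraction * copies}


def secondary_periods(
    md_points: list[MDPoint],
    region: HORArrayRegion,
    min_fraction: float = 0.01,
    min_count: int = 6,
) -> set[int]:
    """Periods above the primary period with weak but structured support.

    Structured variants (e.g. the three deletion doublets of the 25mer array)
    produce repeats longer than the HOR itself — the 34-monomer tertiary
    period.  Requires at least ``min_count`` points and ``min_fraction`` of
    the region's MD points, but less support than the primary period.
    """
    pts = _region_points(md_points, region)
    n = region.primary_period
    counts = Counter(p.period for p in pts if p.period is not None)
    primary_count = counts.get(n, 0)
    total = sum(1 for p in pts if p.period is not None)
    out = set()
    for p, c in counts.items():
        if p > n and c >= max(min_count, min_fraction * total) and c < primary_count:
            out.add(p)
    return out


def _support_table(pts: list[MDPoint]) -> tuple[Counter, int]:
    counts = Counter(p.period for p in pts if p.period is not None)
    return counts, max(1, sum(counts.values()))


def detect_hor_arrays(
    md_points: list[MDPoint],
    min_region_monomers: int = 50,
    support_fraction: float = 0.20,
    breaks: list[int] | None = None,
    track: MonomerTrack | None = None,
) -> list[HORArrayRegion]:
    """Find enumeration spans whose MD points concentrate on an HOR period.

    Spans are cut at recorded inter-array breaks; within each span the
    primary period is the largest period holding at least ``support_fraction`` of the MD points —
    in a canonical cascading 15mer only 5 of 15 monomers carry the full
    period, so the primary line holds ~1/3 of points while subfragment lines
    can hold more.  Subfragment and secondary period sets are attached.
    """
    if not md_points:
        return []
    if breaks is None and track is not None:
        breaks = track.breaks
    breaks = sorted(breaks or [])
    first = md_points[0].enumeration_index
    last = md_points[-1].enumeration_index
    bounds = [first] + [b + 1 for b in breaks if first < b < last] + [last + 1]
    spans = [(lo, hi - 1) for lo, hi in zip(bounds[:-1], bounds[1:]) if hi - lo >= 1]
    regions: list[HORArrayRegion] = []
    gpos = (
        {m.enumeration_index: (m.start, m.end) for m in track.enumerated()}
        if track is not None
        else {}
    )
    for lo, hi in spans:
        if hi - lo + 1 < min_region_monomers:
            continue
        pts = [p for p in md_points if lo <= p.enumeration_index <= hi]
        counts, total = _support_table(pts)
        eligible = {p: c / total for p, c in counts.items() if c / total >= support_fraction}
        if not eligible:
            continue
        n = max(eligible)
        region = HORArrayRegion(lo, hi, n, eligible[n])
        if gpos:
            region.genomic_span = (gpos[lo][0], gpos[hi][1])
        region.subfragment_periods = subfragment_periods(md_points, region)
        region.secondary_periods = secondary_periods(md_points, region)
        regions.append(region)
    return regions


def _cyclic_key(gram: tuple[int, ...]) -> tuple[int, ...]:
    return min(gram[i:] + gram[:i] for i in range(len(gram)))


def _best_cyclic_class(seq: list[int], m: int, preferred_start: int | None = None):
    """Most frequent cyclic equivalence class of m-grams in ``seq``.

    Returns ``(count, anchored_gram)`` or ``None`` if ``seq`` is too short.
    The anchor is the earliest occurrence of the winning class that starts a
    tandem repetition (the next m-gram repeats it), so the unit's rotation
    corresponds to a copy boundary; anchors beginning with ``preferred_start``
    (the primary unit's start type, for interspersed alternates) win over
    other tandem anchors.  A class never occurring in tandem anchors at its
    earliest occurrence.
    """
    if len(seq) < m:
        return None
    counts: Counter = Counter()
    first_at: dict[tuple[int, ...], tuple[int, tuple[int, ...]]] = {}
    for i in range(len(seq) - m + 1):
        gram = tuple(seq[i : i + m])
        key = _cyclic_key(gram)
        counts[key] += 1
        if key not in first_at:
            first_at[key] = (i, gram)
    key, count = max(counts.items(), key=lambda kv: (kv[1], -first_at[kv[0]][0]))
    fallback = None
    for i in range(len(seq) - 2 * m + 1):
        gram = tuple(seq[i : i + m])
        if _cyclic_key(gram) == key and tuple(seq[i + m : i + 2 * m]) == gram:
            if preferred_start is None or gram[0] == preferred_start:
                return count, gram
            if fallback is None:
                fallback = gram
    return count, fallback if fallback is not None else first_at[key][1]


def infer_canonical_unit(
    track: MonomerTrack,
    region: HORArrayRegion,
    interspersed_min_fraction: float = 0.10,
) -> tuple[tuple[int, ...], ...]:
    """The canonical HOR unit(s) of a region, as global family-id sequences.

    The unit is the most frequent cyclic type subsequence of length n,
    anchored at its earliest full occurrence in the region.  If a second,
    non-equivalent unit of length n±1 is well supported the array is
    interspersed (as in the 25mer/26mer case) and both units are returned,
    primary first.  Also populates ``region.local_type_index`` (types
    labelled t1, t2, ... by order of first appearance in the region).
    """
    seq = [
        m.family_id
        for m in track.enumerated()
        if region.first <= m.enumeration_index <= region.last
    ]
    n = region.primary_period
    if len(seq) < 2 * n:
        raise ValueError("region shorter than two primary periods")
    local: dict[int, int] = {}
    for f in seq:
        if f not in local:
            local[f] = len(local) + 1
    region.local_type_index = local
    count, unit = _best_cyclic_class(seq, n)
    unit = tuple(unit)
    alts = []
    for m in (n - 1, n + 1):
        if m < 1:
            continue
        alt = _best_cyclic_class(seq, m, preferred_start=unit[0])
        if alt is None:
            continue
        alt_count, alt_unit = alt
        if alt_count >= max(3, interspersed_min_fraction * count):
            alts.append((alt_count, tuple(alt_unit)))
    # A window of length n±1 sliding over a tandem run of an existing unit is
    # that unit plus duplicated edge types, not a distinct HOR; drop such alts.
    units = [unit]
    for _c, alt_unit in sorted(alts, reverse=True):
        trivial = any(
            _is_tandem_window(alt_unit, kept) for kept in units if len(kept) != len(alt_unit)
        )
        if not trivial:
            units.append(alt_unit)
    if len(units) == 1:
        # single-unit array: refine the rotation so copy boundaries respect
        # the variant structure (interspersed regions keep the tandem anchor)
        units = [_best_rotation(seq, unit)]
    return tuple(units)


def _is_tandem_window(window: tuple[int, ...], unit: tuple[int, ...]) -> bool:
    reps = unit * (len(window) // len(unit) + 2)
    return any(
        reps[i : i + len(window)] == window for i in range(len(reps) - len(window) + 1)
    )


def _segment_spans(
    seq: list[int], units: tuple[tuple[int, ...], ...]
) -> list[tuple[int, int, str]]:
    """Greedy copy segmentation of a family-id sequence.

    Exact occurrences of a unit (longest first) become canonical spans;
    leftover stretches split into variant spans at occurrences of the primary
    unit's start type.  Returns ``(start, end, label)`` index spans covering
    every monomer exactly once.
    """
    anchor = units[0][0]
    by_len = sorted(units, key=len, reverse=True)
    spans: list[tuple[int, int, str]] = []

    def flush(lo: int, hi: int) -> None:
        if lo >= hi:
            return
        cut = lo
        for j in range(lo + 1, hi):
            if seq[j] == anchor:
                spans.append((cut, j, "variant"))
                cut = j
        spans.append((cut, hi, "variant"))

    i = 0
    pending = 0
    n_mono = len(seq)
    while i < n_mono:
        matched = None
        for u in by_len:
            if tuple(seq[i : i + len(u)]) == u:
                matched = u
                break
        if matched is not None:
            flush(pending, i)
            spans.append((i, i + len(matched), "canonical"))
            i += len(matched)
            pending = i
        else:
            i += 1
    flush(pending, n_mono)
    spans.sort()
    return spans


def _best_rotation(seq: list[int], unit: tuple[int, ...]) -> tuple[int, ...]:
    """The rotation of a cyclic unit that segments ``seq`` most parsimoniously.

    In a tandem run every rotation matches equally often, but copy boundaries
    misplaced relative to the array's variant structure split variants into
    extra fragments; the rotation minimising the total copy count is the
    frame in which variants are contiguous sub-blocks of the canonical unit.
    Ties break toward the rotation whose earliest exact occurrence in the
    region comes first.
    """
    rotations = {unit[i:] + unit[:i] for i in range(len(unit))}
    best = None
    for rot in sorted(rotations):
        spans = _segment_spans(seq, (rot,))
        firsts = [
            i for i in range(len(seq) - len(rot) + 1) if tuple(seq[i : i + len(rot)]) == rot
        ]
        first = firsts[0] if firsts else len(seq)
        key = (len(spans), first, rot)
        if best is None or key < best:
            best = key
    return best[2] if best else unit


@dataclass(frozen=True)
class HORCopy:
    """One HOR copy: consecutive monomers, local types and its label."""

    enumeration_indices: tuple[int, ...]
    family_ids: tuple[int, ...]
    local_types: tuple[int, ...]
    label: str  # 'canonical' | 'variant'

    @property
    def signature(self) -> tuple[int, ...]:
        return self.local_types

    def __len__(self) -> int:
        return len(self.family_ids)


def segment_copies(
    track: MonomerTrack,
    region: HORArrayRegion,
    units,
) -> list[HORCopy]:
    """Partition a region into consecutive HOR copies.

    Exact occurrences of a canonical unit (longest unit first at each
    position) become canonical copies; leftover stretches are split into
    variant copies at occurrences of the canonical start type, with any
    monomers before the first start type forming a leading variant.  Every
    monomer belongs to exactly one copy.
    """
    if isinstance(units[0], int):
        units = (tuple(units),)
    units = tuple(tuple(u) for u in units)
    mono = [
        m
        for m in track.enumerated()
        if region.first <= m.enumeration_index <= region.last
    ]
    seq = [m.family_id for m in mono]
    local = region.local_type_index or {}
    if not local:
        for f in seq:
            if f not in local:
                local[f] = len(local) + 1
        region.local_type_index = local
    copies: list[HORCopy] = []
    for lo, hi, label in _segment_spans(seq, units):
        sl = mono[lo:hi]
        copies.append(
            HORCopy(
                tuple(m.enumeration_index for m in sl),
                tuple(m.family_id for m in sl),
                tuple(local.get(m.family_id, 0) for m in sl),
                label,
            )
        )
    return copies


@dataclass
class CascadingScheme:
    """Row/column layout of one HOR copy.

    Columns are the distinct types t1..tτ in order of first appearance; rows
    break whenever the next monomer's type index does not exceed the current
    one, so within each row column indices strictly increase and no type
    repeats in a row.
    """

    types: tuple[int, ...]  # original type values, one per column
    rows: list[list[tuple[int, int]]]  # (column_index 0-based, monomer ordinal 1-based)
    n: int
    n_types: int
    n_rows: int

    def flatten(self) -> list[int]:
        out = []
        for row in self.rows:
            for col, _ord in row:
                out.append(self.types[col])
        return out

    def column_occupancy(self) -> list[int]:
        occ = [0] * self.n_types
        for row in self.rows:
            for col, _ord in row:
                occ[col] += 1
        return occ

    def render(self) -> str:
        width = max(len(str(t)) for t in self.types) + 2
        lines = ["".join(f"t{i+1}".rjust(width) for i in range(self.n_types))]
        for row in self.rows:
            cells = ["".rjust(width)] * self.n_types
            for col, ordinal in row:
                cells[col] = f"m{ordinal}".rjust(width)
            lines.append("".join(cells))
        return "\n".join(lines)


def build_scheme(type_sequence) -> CascadingScheme:
    """Arrange one HOR copy's type sequence into the cascading scheme.

    Walking the monomers in order, a monomer of type t_m following one of type
    t_k starts a new row when m <= k (type indices by order of first
    appearance); otherwise it extends the current row.  Monomers sit in the
    column of their type, so repeated types align vertically.
    """
    seq = list(type_sequence)
    if not seq:
        raise ValueError("type sequence must be non-empty")
    order: dict[int, int] = {}
    for t in seq:
        if t not in order:
            order[t] = len(order)
    rows: list[list[tuple[int, int]]] = [[]]
    prev = -1
    for ordinal, t in enumerate(seq, start=1):
        col = order[t]
        if rows[-1] and col <= prev:
            rows.append([])
        rows[-1].append((col, ordinal))
        prev = col
    types = tuple(sorted(order, key=order.get))
    return CascadingScheme(types, rows, len(seq), len(order), len(rows))


@dataclass(frozen=True)
class UnitComparison:
    shared: int
    unique_to_a: frozenset
    unique_to_b: frozenset


def compare_units(unit_a, unit_b) -> UnitComparison:
    """Shared and unique monomer types between two canonical units.

    Both units must be expressed over the same global family ids (not local
    per-region relabels) for the comparison to be meaningful.
    """
    a, b = set(unit_a), set(unit_b)
    return UnitComparison(len(a & b), frozenset(a - b), frozenset(b - a))
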