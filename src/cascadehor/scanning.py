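"""Base-by-base consensus scan of the assembly and tandem enumeration.

Every family consensus (direct and reverse complement) is searched across the
whole sequence; overlapping hits are resolved greedily by divergence so the
reported track is the non-overlapping best-hit tiling.  Tandemly arranged
monomers are then enumerated 1..N in genomic order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib
import numpy as np

from .families import MonomerFamily
from .simulate import reverse_complement

__all__ = ["MonomerInstance", "MonomerTrack", "scan", "tandem_enumerate"]


@dataclass(frozen=True)
class MonomerInstance:
    """One monomer located on the assembly (0-based half-open interval)."""

    start: int
    end: int
    strand: str
    family_id: int
    divergence: float
    enumeration_index: int | None = None


@dataclass
class MonomerTrack:
    """Ordered, non-overlapping monomer instances plus scan provenance."""

    instances: list[MonomerInstance]
    assembly_id: str = ""
    params: dict = field(default_factory=dict)
    # enumeration indices after which an inter-array break was recorded
    breaks: list[int] = field(default_factory=list)

    def enumerated(self) -> list[MonomerInstance]:
        return [m for m in self.instances if m.enumeration_index is not None]

    def family_sequence(self) -> list[int]:
        return [m.family_id for m in self.enumerated()]


def _consensus_map(consensi) -> dict[int, str]:
    if isinstance(consensi, dict):
        return dict(consensi)
    out = {}
    for item in consensi:
        if isinstance(item, MonomerFamily):
            out[item.family_id] = item.consensus
        else:
            out[len(out)] = item
    return out


def _extract_hits(query: str, target: str, k: int) -> list[tuple[int, int, int]]:
    """All matches of ``query`` in ``target`` with edit distance <= ``k``.

    Iterative best-hit extraction: edlib (infix mode) reports every location
    tied at the current best distance; those loci are masked and the search
    repeats until the best exceeds ``k``.  Returns (start, end_exclusive,
    distance) triples; slightly shifted echoes of masked hits are resolved by
    the caller's overlap rule.
    """
    work = bytearray(target.encode())
    hits: list[tuple[int, int, int]] = []
    while True:
        res = edlib.align(query, bytes(work), mode="HW", task="locations", k=k)
        d = res["editDistance"]
        if d < 0:
            break
        locs = res["locations"]
        if not locs:
            break
        if len(locs) > 50000:  # safety valve against pathological tie floods
            locs = locs[:50000]
        for s, e in locs:
            s = 0 if s is None else s
            hits.append((s, e + 1, d))
        for s, e in locs:
            s = 0 if s is None else s
            work[s : e + 1] = b"\x23" * (e + 1 - s)  # mask with non-base byte
    return hits


def scan(
    sequence: str,
    consensi,
    accept_threshold: float = 25.0,
    min_length_fraction: float = 0.8,
    assembly_id: str = "",
) -> MonomerTrack:
    """Locate every monomer of every family on both strands.

    A hit is accepted when its divergence to the best-matching consensus,
    ``100*d/max(len(consensus), span)``, is at most ``accept_threshold``
    (within-type divergence is <5%, between-type 20-40%, so 25% separates true
    monomers from flank noise).  Overlaps are resolved greedily by ascending
    divergence, then leftmost start, then lowest family id; a later candidate
    overlapping an accepted instance is trimmed to the free interval and kept
    only if at least ``min_length_fraction`` of the consensus length survives.
    """
    cmap = _consensus_map(consensi)
    if not cmap:
        raise ValueError("scan requires at least one consensus")
    seq = sequence.upper()
    candidates: list[tuple[float, int, int, int, str]] = []
    for fid in sorted(cmap):
        cons = cmap[fid].upper()
        k = int(len(cons) * accept_threshold / (100.0 - accept_threshold)) + 1
        for strand, query in (("+", cons), ("-", reverse_complement(cons))):
            for s, e, d in _extract_hits(query, seq, k):
                div = 100.0 * d / max(len(cons), e - s)
                if div <= accept_threshold:
                    candidates.append((div, s, fid, e, strand))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    import bisect

    accepted: list[MonomerInstance] = []  # kept sorted by start
    starts: list[int] = []
    for div, s, fid, e, strand in candidates:
        idx = bisect.bisect_left(starts, s)
        lo = s if idx == 0 else max(s, accepted[idx - 1].end)
        hi = e if idx == len(starts) else min(e, accepted[idx].start)
        if hi - lo < min_length_fraction * len(cmap[fid]):
            continue
        inst = MonomerInstance(lo, hi, strand, fid, round(div, 4))
        accepted.insert(idx, inst)
        starts.insert(idx, lo)
    return MonomerTrack(
        instances=accepted,
        assembly_id=assembly_id,
        params={
            "accept_threshold": accept_threshold,
            "min_length_fraction": min_length_fraction,
            "n_consensi": len(cmap),
        },
    )


def tandem_enumerate(
    track: MonomerTrack,
    max_gap_fraction: float = 0.5,
    break_gap_monomers: int = 10,
) -> MonomerTrack:
    """Number tandemly arranged monomers 1..N in genomic order.

    An instance is tandem when the gap to its nearest neighbour is at most
    ``max_gap_fraction`` times the typical monomer length; isolated instances
    stay in the track without an enumeration index.  Enumeration runs across
    inter-array gaps, but gaps wider than ``break_gap_monomers`` monomer
    lengths are recorded as array breaks.
    """
    if not track.instances:
        return replace(track)
    inst = sorted(track.instances, key=lambda m: m.start)
    unit = float(np.median([m.end - m.start for m in inst]))
    max_gap = max_gap_fraction * unit
    n = len(inst)
    tandem = []
    for i, m in enumerate(inst):
        gap_prev = m.start - inst[i - 1].end if i > 0 else None
        gap_next = inst[i + 1].start - m.end if i < n - 1 else None
        near = [g for g in (gap_prev, gap_next) if g is not None]
        tandem.append(bool(near) and min(near) <= max_gap)
    out: list[MonomerInstance] = []
    breaks: list[int] = []
    idx = 0
    prev_end: int | None = None
    for m, is_t in zip(inst, tandem):
        if is_t:
            idx += 1
            if prev_end is not None and m.start - prev_end > break_gap_monomers * unit:
                breaks.append(idx - 1)
            out.append(replace(m, enumeration_index=idx))
            prev_end = m.end
        else:
            out.append(replace(m, enumeration_index=None))
    new = MonomerTrack(out, track.assembly_id, dict(track.params), breaks)
    new.params["max_gap_fraction"] = max_gap_fraction
    return new
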