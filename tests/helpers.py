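"""Independent oracles and small builders shared across the test suite."""

from __future__ import annotations

import bisect
from collections import Counter, defaultdict

import numpy as np

from cascadehor.scanning import MonomerInstance, MonomerTrack


def dp_edit_distance(a: str, b: str) -> int:
    """Textbook O(nm) Levenshtein dynamic programme (unit costs)."""
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a, start=1):
        cur = np.empty(len(b) + 1, dtype=np.int64)
        cur[0] = i
        for j, cb in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return int(prev[-1])


def dp_divergence(a: str, b: str) -> float:
    return 100.0 * dp_edit_distance(a, b) / max(len(a), len(b))


def brute_md_periods(types: list[int]) -> list[int | None]:
    """O(N^2) next-same-type search — the MD oracle."""
    out: list[int | None] = []
    for i, t in enumerate(types):
        period = None
        for j in range(i + 1, len(types)):
            if types[j] == t:
                period = j - i
                break
        out.append(period)
    return out


def track_from_types(types: list[int], unit: int = 171) -> MonomerTrack:
    """A synthetic enumerated track with one monomer per type label."""
    inst = [
        MonomerInstance(i * unit, (i + 1) * unit, "+", t, 0.0, enumeration_index=i + 1)
        for i, t in enumerate(types)
    ]
    return MonomerTrack(inst)


def label_accuracy(track, truth) -> tuple[float, int]:
    """Fraction of scanned monomers carrying the majority-mapped planted type.

    Each enumerated instance is matched to the planted monomer with maximal
    overlap (requiring >=50% of the instance); recovered families are mapped
    onto planted types by majority vote over those matches.
    """
    planted = truth.monomers
    starts = [m.start for m in planted]
    pairs = []
    for m in track.enumerated():
        i = bisect.bisect_right(starts, m.start) - 1
        best = None
        for j in (i, i + 1):
            if 0 <= j < len(planted):
                ov = min(m.end, planted[j].end) - max(m.start, planted[j].start)
                if ov > 0 and (best is None or ov > best[0]):
                    best = (ov, planted[j].type_index)
        if best and best[0] >= 0.5 * (m.end - m.start):
            pairs.append((m.family_id, best[1]))
    votes: dict[int, Counter] = defaultdict(Counter)
    for f, t in pairs:
        votes[f][t] += 1
    mapping = {f: c.most_common(1)[0][0] for f, c in votes.items()}
    ok = sum(1 for f, t in pairs if mapping[f] == t)
    return ok / len(pairs), len(pairs)
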