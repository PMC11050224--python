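"""Monomer families: pairwise divergence, 5% clustering and per-family consensus.

Alpha satellite monomers that differ by less than 5% belong to the same monomer
type (family), while distinct types within one HOR copy differ by roughly
20-40%.  This module computes the all-vs-all divergence matrix over candidate
monomers, cuts an average-linkage dendrogram at the family threshold, and
builds one consensus sequence per family via a star alignment onto a
medoid-length reference.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as _scipy_linkage
from scipy.spatial.distance import squareform

__all__ = [
    "MonomerFamily",
    "divergence",
    "divergence_matrix",
    "cluster_families",
    "consensus",
    "build_families",
    "cyclic_divergence",
    "merge_rotated_families",
]

#: divergence value assigned to pairs whose edit distance exceeds the search cap
SATURATED = 100.0


@dataclass(frozen=True)
class MonomerFamily:
    """One monomer type: identifier, consensus sequence and member count."""

    family_id: int
    consensus: str
    member_count: int

    @property
    def low_support(self) -> bool:
        """Families with fewer than 3 members are retained but flagged."""
        return self.member_count < 3


def divergence(a: str, b: str) -> float:
    """Percent divergence between two sequences.

    Defined as ``100 * edit_distance(a, b) / max(len(a), len(b))`` using a
    global (end-to-end) alignment with unit costs.  Symmetric, zero for
    identical strings, and bounded by 100 for same-length strings.
    """
    if not a or not b:
        raise ValueError("divergence requires two non-empty sequences")
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 100.0 * d / max(len(a), len(b))


def divergence_matrix(monomers: list[str], cap: float | None = None) -> np.ndarray:
    """Symmetric percent-divergence matrix over ``monomers``.

    ``cap`` (percent) bounds the edit-distance search: pairs more divergent
    than the cap are reported as :data:`SATURATED` (100).  Distinct monomer
    types sit at >=20% divergence, far above any clustering threshold in use,
    so capping changes no family decision but speeds the all-vs-all pass.
    """
    if not monomers:
        raise ValueError("divergence_matrix requires at least one monomer")
    n = len(monomers)
    mat = np.zeros((n, n), dtype=float)
    for i in range(n):
        li = len(monomers[i])
        for j in range(i + 1, n):
            m = max(li, len(monomers[j]))
            if cap is None:
                d = edlib.align(monomers[i], monomers[j], mode="NW", task="distance")[
                    "editDistance"
                ]
                val = 100.0 * d / m
            else:
                k = int(math.ceil(cap / 100.0 * m))
                d = edlib.align(
                    monomers[i], monomers[j], mode="NW", task="distance", k=k
                )["editDistance"]
                val = 100.0 * d / m if d >= 0 else SATURATED
            mat[i, j] = mat[j, i] = val
    return mat


def cluster_families(
    matrix: np.ndarray, threshold: float = 5.0, method: str = "average"
) -> list[int]:
    """Partition monomer indices into families at ``threshold`` percent.

    Agglomerative clustering (``single``/``average``/``complete`` linkage) cut
    so that clusters merged at a height *strictly below* the threshold form one
    family ("differ from each other by less than 5%").  Returns one 0-based
    family label per monomer, numbered by first occurrence.
    """
    n = matrix.shape[0]
    if n == 1:
        return [0]
    if method not in ("single", "average", "complete"):
        raise ValueError(f"unknown linkage {method!r}")
    condensed = squareform(np.asarray(matrix, dtype=float), checks=False)
    z = _scipy_linkage(condensed, method=method)
    raw = fcluster(z, t=threshold - 1e-9, criterion="distance")
    remap: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap)
        labels.append(remap[r])
    return labels


def _expand_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def consensus(members: list[str]) -> str:
    """Column-majority consensus of a family.

    A star alignment: every member is globally aligned onto a reference member
    of median length, bases are tallied per reference column (plus one slot for
    single-base insertions after each column), and the majority symbol wins.
    Gap-majority columns are dropped; base ties break alphabetically.  With a
    single member the member itself is returned verbatim.
    """
    if not members:
        raise ValueError("consensus requires at least one member")
    if len(members) == 1:
        return members[0]
    ordered = sorted(members)
    by_len = sorted(ordered, key=len)
    ref = by_len[(len(by_len) - 1) // 2]
    l = len(ref)
    counts = [Counter() for _ in range(l)]        # per-column base/gap tallies
    inserts = [Counter() for _ in range(l + 1)]   # first inserted base after col
    ins_members = np.zeros(l + 1, dtype=int)
    for mem in ordered:
        res = edlib.align(mem, ref, mode="NW", task="path")
        qi = ti = 0
        for length, op in _expand_cigar(res["cigar"]):
            if op in ("=", "X"):
                for _ in range(length):
                    counts[ti][mem[qi]] += 1
                    qi += 1
                    ti += 1
            elif op == "D":  # consumes reference only: member has a gap
                for _ in range(length):
                    counts[ti]["-"] += 1
                    ti += 1
            elif op == "I":  # consumes member only: insertion relative to ref
                inserts[ti][mem[qi]] += 1
                ins_members[ti] += 1
                qi += length
            else:  # pragma: no cover - edlib emits only =,X,I,D
                raise ValueError(f"unexpected cigar op {op!r}")
    half = len(members) / 2.0
    out: list[str] = []
    for col in range(l + 1):
        if ins_members[col] > half:
            base, _ = min(inserts[col].items(), key=lambda kv: (-kv[1], kv[0]))
            out.append(base)
        if col < l:
            base, n = min(counts[col].items(), key=lambda kv: (-kv[1], kv[0]))
            if base != "-":
                out.append(base)
    return "".join(out)


def build_families(
    monomers: list[str],
    threshold: float = 5.0,
    method: str = "average",
    cap: float | None = 15.0,
) -> tuple[list[MonomerFamily], list[int]]:
    """Cluster candidate monomers and build one consensus per family.

    Monomers are put in canonical (lexicographic) order before clustering so
    the partition is invariant under permutation of the input; family ids are
    then assigned by first occurrence in the original (genomic) order.
    Returns ``(families, labels)`` with one family label per input monomer.
    """
    if not monomers:
        raise ValueError("no monomers to cluster")
    order = sorted(range(len(monomers)), key=lambda i: monomers[i])
    mat = divergence_matrix([monomers[i] for i in order], cap=cap)
    canon_labels = cluster_families(mat, threshold=threshold, method=method)
    raw = [0] * len(monomers)
    for pos, orig in enumerate(order):
        raw[orig] = canon_labels[pos]
    remap: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap)
        labels.append(remap[r])
    members: dict[int, list[str]] = {}
    for lab, seq in zip(labels, monomers):
        members.setdefault(lab, []).append(seq)
    families = [
        MonomerFamily(fid, consensus(members[fid]), len(members[fid]))
        for fid in sorted(members)
    ]
    return families, labels


def cyclic_divergence(a: str, b: str) -> float:
    """Minimum percent divergence of ``a`` against any rotation of ``b``.

    Computed as an infix alignment of ``a`` against ``b+b``, which scores every
    rotation of ``b`` (and nearby offsets) in one pass.
    """
    if not a or not b:
        raise ValueError("cyclic_divergence requires non-empty sequences")
    d = edlib.align(a, b + b, mode="HW", task="distance")["editDistance"]
    return 100.0 * d / len(a)


def merge_rotated_families(
    families: list[MonomerFamily], threshold: float = 5.0
) -> tuple[list[MonomerFamily], dict[int, int]]:
    """Drop families whose consensus is a rotation of a better-supported one.

    Tiling a tandem array with a fixed period produces phase-shifted duplicates
    of the true monomer types whenever indels make the phase drift.  Such
    duplicates are rotations of the dominant family consensus; they are removed
    here (largest family wins, ties to the lower id) and the subsequent
    consensus scan re-labels their genomic loci correctly.  Returns the kept
    families and a mapping ``dropped_id -> kept_id``.
    """
    kept: list[MonomerFamily] = []
    merged: dict[int, int] = {}
    for fam in sorted(families, key=lambda f: (-f.member_count, f.family_id)):
        target = None
        for other in kept:
            if cyclic_divergence(fam.consensus, other.consensus) < threshold:
                target = other.family_id
                break
        if target is None:
            kept.append(fam)
        else:
            merged[fam.family_id] = target
    kept.sort(key=lambda f: f.family_id)
    return kept, merged
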