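"""Synthetic alpha-satellite assemblies with planted HOR structure.

Generates monomer type libraries (~171 bp units, inter-type divergence in the
20-40% band, intra-type divergence well below 5%), tandem HOR arrays following
the canonical cascading/Willard's layouts, variant copies, deletion doublets,
strand flips and random flanks — together with exact ground truth, so the
discovery pipeline can be tested against known structure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .families import divergence

__all__ = [
    "FamilyLibrary",
    "PlantSpec",
    "TruthMonomer",
    "SyntheticTruth",
    "make_family_library",
    "make_hor_array",
    "make_assembly",
    "mutate",
    "reverse_complement",
    "UNIT_15MER",
    "UNIT_20MER",
    "UNIT_18MER",
    "GLOBAL_TYPES_25_26",
    "UNIT_25MER",
    "UNIT_26MER",
    "DOUBLET_FIRST",
    "DOUBLET_SECOND",
    "preset_copy_schemes",
    "doublet_25mer_schemes",
    "mixed_15mer_schemes",
    "make_preset_assembly",
    "PRESETS",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

# ---------------------------------------------------------------------------
# Canonical HOR unit layouts (1-based type indices into a family library).
# ---------------------------------------------------------------------------

#: Canonical cascading 15mer: 15 monomers of 9 types in four rows
#: (t1 t2 t3 t4 | t1 t2 t5 t6 t7 | t3 t8 t9 | t2 t3 t4).
UNIT_15MER = (1, 2, 3, 4, 1, 2, 5, 6, 7, 3, 8, 9, 2, 3, 4)

#: Canonical cascading 20mer: 20 monomers of 19 types, only t9 repeated.
UNIT_20MER = tuple(range(1, 14)) + (9,) + tuple(range(14, 20))

#: Willard's-type 18mer: every monomer a distinct type.
UNIT_18MER = tuple(range(1, 19))

#: The interspersed 25mer/26mer pair shares 22 of 29 global types: the 25mer
#: lacks t11, t16, t17, t28 and the 26mer lacks t10, t15, t27.
GLOBAL_TYPES_25_26 = tuple(range(1, 30))
UNIT_25MER = tuple(t for t in GLOBAL_TYPES_25_26 if t not in (11, 16, 17, 28))
UNIT_26MER = tuple(t for t in GLOBAL_TYPES_25_26 if t not in (10, 15, 27))

#: Deletion-doublet members of the 25mer array: the first member keeps
#: m1-m12 (m13-m25 deleted), the second keeps m4-m25 (m1-m3 deleted); the
#: 12 + 22 = 34 monomer hybrid produces the tertiary period 34.
DOUBLET_FIRST = UNIT_25MER[:12]
DOUBLET_SECOND = UNIT_25MER[3:]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def mutate(seq: str, rate: float, rng: np.random.Generator, indel_fraction: float = 0.01) -> str:
    """Mutate ``seq`` with per-base substitutions at ``rate``.

    A fraction ``indel_fraction`` of mutation events are single-base indels
    (insertion or deletion with equal probability) so that downstream scanning
    must tolerate length jitter, as real arrays demand.
    """
    if rate <= 0:
        return seq
    out = []
    for base in seq:
        if rng.random() < rate:
            if rng.random() < indel_fraction:
                if rng.random() < 0.5:
                    continue  # deletion
                out.append(base)
                out.append(_BASES[rng.integers(4)])  # insertion after base
            else:
                others = _BASES.replace(base.upper(), "") or _BASES
                out.append(others[rng.integers(len(others))])
        else:
            out.append(base)
    return "".join(out)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilyLibrary:
    """An ordered library of monomer type consensus sequences."""

    type_count: int
    monomer_length: int
    consensi: tuple[str, ...]
    min_inter_divergence: float
    seed: int

    def consensus_of(self, type_index: int) -> str:
        """Consensus for a 1-based type index."""
        return self.consensi[type_index - 1]


@dataclass(frozen=True)
class PlantSpec:
    """How to emit one tandem HOR array.

    ``copy_schemes`` holds one type-index sequence per HOR copy, e.g. the
    canonical 15mer ``(1,2,3,4,1,2,5,6,7,3,8,9,2,3,4)``; indices are 1-based
    into the library.
    """

    copy_schemes: tuple[tuple[int, ...], ...]
    intra_divergence: float = 1.0
    strand: str = "+"
    flank_length: int = 0
    seed: int = 0

    def validate(self, library: FamilyLibrary) -> None:
        if not self.copy_schemes:
            raise ValueError("copy_schemes must contain at least one copy")
        if not (0 <= self.intra_divergence < 5):
            raise ValueError("intra_divergence must lie in [0, 5)")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        for scheme in self.copy_schemes:
            for t in scheme:
                if not 1 <= t <= library.type_count:
                    raise ValueError(f"type index {t} not in library")


@dataclass(frozen=True)
class TruthMonomer:
    start: int
    end: int  # 0-based half-open on the emitted forward strand
    strand: str
    type_index: int
    copy_index: int


@dataclass
class SyntheticTruth:
    """Planted intervals, copy labels and array boundaries for a fixture."""

    monomers: list[TruthMonomer] = field(default_factory=list)
    copy_labels: list[str] = field(default_factory=list)
    copy_schemes: list[tuple[int, ...]] = field(default_factory=list)
    array_bounds: list[tuple[int, int]] = field(default_factory=list)

    def shifted(self, offset: int) -> "SyntheticTruth":
        return SyntheticTruth(
            [
                TruthMonomer(m.start + offset, m.end + offset, m.strand, m.type_index, m.copy_index)
                for m in self.monomers
            ],
            list(self.copy_labels),
            list(self.copy_schemes),
            [(a + offset, b + offset) for a, b in self.array_bounds],
        )

    def to_bed(self) -> str:
        lines = [
            f"synthetic\t{m.start}\t{m.end}\t{m.type_index}\t{m.copy_index}\t{m.strand}"
            for m in self.monomers
        ]
        return "\n".join(lines) + "\n"

    def labels_json(self) -> str:
        return json.dumps(
            {
                "copy_labels": self.copy_labels,
                "copy_schemes": [list(s) for s in self.copy_schemes],
                "array_bounds": [list(b) for b in self.array_bounds],
            },
            indent=1,
        )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _ancestor_rate(target_pairwise: float) -> float:
    # Two lineages mutated independently at rate r from one ancestor differ at
    # a site with probability 2r(1-r) + (2/3)r^2; invert for r.
    d = min(target_pairwise, 0.72)
    return (2.0 - math.sqrt(4.0 - (16.0 / 3.0) * d)) / (8.0 / 3.0)


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i, base in enumerate(out):
        if rng.random() < rate:
            others = _BASES.replace(base, "")
            out[i] = others[rng.integers(3)]
    return "".join(out)


def make_family_library(
    type_count: int,
    monomer_length: int = 171,
    min_inter_divergence: float = 20.0,
    seed: int = 0,
    max_attempts: int = 1000,
) -> FamilyLibrary:
    """Generate ``type_count`` monomer type consensi.

    Types descend from one random ancestor at a substitution rate calibrated so
    pairwise divergences land in the 20-40% band observed between alpha
    satellite types; rejection sampling enforces ``min_inter_divergence``.
    Deterministic for a fixed seed.
    """
    if type_count < 1:
        raise ValueError("type_count must be >= 1")
    if min_inter_divergence > 60:
        raise ValueError("min_inter_divergence above 60% is unsatisfiable")
    rng = np.random.default_rng([101, seed])
    ancestor = _random_seq(rng, monomer_length)
    rate = _ancestor_rate(min_inter_divergence / 100.0 + 0.08)
    consensi: list[str] = []
    for _ in range(type_count):
        for _attempt in range(max_attempts):
            cand = _substitute(ancestor, rate, rng)
            if all(divergence(cand, prev) >= min_inter_divergence for prev in consensi):
                consensi.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place type {len(consensi) + 1} at "
                f">={min_inter_divergence}% divergence in {max_attempts} attempts"
            )
    return FamilyLibrary(
        type_count=type_count,
        monomer_length=monomer_length,
        consensi=tuple(consensi),
        min_inter_divergence=min_inter_divergence,
        seed=seed,
    )


def make_hor_array(library: FamilyLibrary, spec: PlantSpec) -> tuple[str, SyntheticTruth]:
    """Emit one tandem HOR array plus ground truth.

    Each monomer is an independently mutated copy of its type consensus; the
    whole array is reverse-complemented when ``spec.strand`` is '-'.  Copies
    whose scheme equals the modal scheme are labelled canonical.
    """
    spec.validate(library)
    rng = np.random.default_rng([102, spec.seed])
    rate = spec.intra_divergence / 100.0
    pieces: list[str] = []
    monomers: list[TruthMonomer] = []
    pos = 0
    for copy_idx, scheme in enumerate(spec.copy_schemes):
        for t in scheme:
            mono = mutate(library.consensus_of(t), rate, rng)
            pieces.append(mono)
            monomers.append(TruthMonomer(pos, pos + len(mono), "+", t, copy_idx))
            pos += len(mono)
    seq = "".join(pieces)
    scheme_counts: dict[tuple[int, ...], int] = {}
    for scheme in spec.copy_schemes:
        scheme_counts[scheme] = scheme_counts.get(scheme, 0) + 1
    modal = max(scheme_counts.items(), key=lambda kv: (kv[1], -len(kv[0])))[0]
    labels = ["canonical" if s == modal else "variant" for s in spec.copy_schemes]
    if spec.strand == "-":
        total = len(seq)
        seq = reverse_complement(seq)
        monomers = [
            TruthMonomer(total - m.end, total - m.start, "-", m.type_index, m.copy_index)
            for m in reversed(monomers)
        ]
    truth = SyntheticTruth(
        monomers=monomers,
        copy_labels=labels,
        copy_schemes=[tuple(s) for s in spec.copy_schemes],
        array_bounds=[(0, len(seq))],
    )
    return seq, truth


def make_assembly(
    arrays: list[tuple[str, SyntheticTruth]],
    flank_length: int = 10000,
    seed: int = 0,
) -> tuple[str, SyntheticTruth]:
    """Join arrays with i.i.d. random flanks; merge and shift the truth."""
    if not arrays:
        raise ValueError("make_assembly requires at least one array")
    rng = np.random.default_rng([103, seed])
    pieces: list[str] = []
    merged = SyntheticTruth()
    pos = 0
    for seq, truth in arrays:
        if flank_length:
            pieces.append(_random_seq(rng, flank_length))
            pos += flank_length
        shifted = truth.shifted(pos)
        merged.monomers.extend(shifted.monomers)
        merged.copy_labels.extend(shifted.copy_labels)
        merged.copy_schemes.extend(shifted.copy_schemes)
        merged.array_bounds.extend(shifted.array_bounds)
        pieces.append(seq)
        pos += len(seq)
    if flank_length:
        pieces.append(_random_seq(rng, flank_length))
    return "".join(pieces), merged


# ---------------------------------------------------------------------------
# Presets mirroring the four chromosome-15 array layouts
# ---------------------------------------------------------------------------

PRESETS = ("15mer", "20mer", "18mer", "25-26mer", "chr15-like")


def doublet_25mer_schemes(n_copies: int) -> tuple[tuple[int, ...], ...]:
    """48-copy-style 25mer array with deletion doublets at copies 8/9, 11/12, 14/15."""
    first = {8, 11, 14}
    second = {9, 12, 15}
    schemes = []
    for c in range(1, n_copies + 1):
        if c in first:
            schemes.append(DOUBLET_FIRST)
        elif c in second:
            schemes.append(DOUBLET_SECOND)
        else:
            schemes.append(UNIT_25MER)
    return tuple(schemes)


def _interspersed_25_26_schemes(lower_copies: int = 48) -> tuple[tuple[int, ...], ...]:
    """Fig-8a layout: 4x26, 1x25, 3x26, 2x25, 7x26, then the 25mer block with doublets."""
    top: list[tuple[int, ...]] = []
    for count, unit in ((4, UNIT_26MER), (1, UNIT_25MER), (3, UNIT_26MER),
                        (2, UNIT_25MER), (7, UNIT_26MER)):
        top.extend([unit] * count)
    return tuple(top) + doublet_25mer_schemes(lower_copies)


def mixed_15mer_schemes(
    n_copies: int, canonical_fraction: float, seed: int
) -> tuple[tuple[int, ...], ...]:
    """A 15mer array with the given canonical fraction.

    Variant copies are the pronounced "first row deleted" 11mer variant
    (monomers m5-m15); variant positions are drawn uniformly at random.
    """
    variant = UNIT_15MER[4:]
    n_var = int(round(n_copies * (1.0 - canonical_fraction)))
    rng = np.random.default_rng([104, seed])
    var_pos = set(rng.choice(n_copies, size=n_var, replace=False).tolist())
    return tuple(variant if i in var_pos else UNIT_15MER for i in range(n_copies))


def preset_copy_schemes(name: str, n_copies: int | None = None) -> tuple[tuple[int, ...], ...]:
    """Copy schemes (1-based type indices) for a named array preset."""
    if name == "15mer":
        return (UNIT_15MER,) * (n_copies or 50)
    if name == "20mer":
        return (UNIT_20MER,) * (n_copies or 50)
    if name == "18mer":
        return (UNIT_18MER,) * (n_copies or 12)
    if name == "25-26mer":
        return _interspersed_25_26_schemes(n_copies or 48)
    raise ValueError(f"unknown preset {name!r}")


def _offset_schemes(schemes, offset):
    return tuple(tuple(t + offset for t in s) for s in schemes)


def make_preset_assembly(
    name: str,
    seed: int = 0,
    intra_divergence: float = 1.0,
    flank_length: int = 10000,
    n_copies: int | None = None,
    canonical_fraction: float | None = None,
) -> tuple[str, SyntheticTruth]:
    """Build a ready-to-analyse assembly for one of the named presets.

    ``chr15-like`` emulates the chromosome-15 layout: an 18mer Willard's
    array, the interspersed 25/26mer array, the cascading 20mer and the
    cascading 15mer, in genomic order, over one shared type library.
    """
    if name != "chr15-like":
        n_types = {"15mer": 9, "20mer": 19, "18mer": 18, "25-26mer": 29}[name]
        lib = make_family_library(n_types, seed=seed)
        if name == "15mer" and canonical_fraction is not None:
            schemes = mixed_15mer_schemes(n_copies or 60, canonical_fraction, seed + 1)
        else:
            schemes = preset_copy_schemes(name, n_copies)
        seq, truth = make_hor_array(
            lib, PlantSpec(schemes, intra_divergence=intra_divergence, seed=seed + 2)
        )
        return make_assembly([(seq, truth)], flank_length=flank_length, seed=seed + 3)

    lib = make_family_library(9 + 19 + 18 + 29, seed=seed)
    layout = [
        ("18mer", preset_copy_schemes("18mer", 12), 9 + 19),
        ("25-26mer", _interspersed_25_26_schemes(20), 9 + 19 + 18),
        ("20mer", preset_copy_schemes("20mer", 20), 9),
        ("15mer", mixed_15mer_schemes(24, 0.65, seed + 7), 0),
    ]
    arrays = []
    for i, (_aname, schemes, offset) in enumerate(layout):
        arrays.append(
            make_hor_array(
                lib,
                PlantSpec(
                    _offset_schemes(schemes, offset),
                    intra_divergence=intra_divergence,
                    seed=seed + 10 + i,
                ),
            )
        )
    return make_assembly(arrays, flank_length=flank_length, seed=seed + 20)
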