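"""MD series, period spectra, canonical units, copies and cascading schemes."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cascadehor.hor import (
    build_scheme,
    compare_units,
    detect_hor_arrays,
    infer_canonical_unit,
    md_series,
    monomer_grm_spectrum,
    secondary_periods,
    segment_copies,
    subfragment_periods,
)
from cascadehor.simulate import (
    DOUBLET_FIRST,
    DOUBLET_SECOND,
    UNIT_15MER,
    UNIT_18MER,
    UNIT_20MER,
    UNIT_25MER,
    UNIT_26MER,
    doublet_25mer_schemes,
)

from helpers import brute_md_periods, track_from_types


def _flat(schemes):
    return [t for s in schemes for t in s]


class TestMDSeries:
    def test_next_same_type_distance(self):
        track = track_from_types([1, 2, 3, 1, 2])
        periods = [p.period for p in md_series(track)]
        assert periods == [3, 3, None, None, None]

    def test_all_distinct_families_no_periods(self):
        track = track_from_types(list(range(10)))
        assert all(p.period is None for p in md_series(track))

    def test_matches_brute_force_oracle_on_random_tracks(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            types = rng.integers(0, 12, size=400).tolist()
            got = [p.period for p in md_series(track_from_types(types))]
            assert got == brute_md_periods(types)

    def test_interior_15mer_copy_period_multiset(self):
        """An interior canonical 15mer copy carries periods {4 x6, 7 x2, 11 x2, 15 x5}."""
        types = _flat([UNIT_15MER] * 5)
        oracle = brute_md_periods(types)
        interior = Counter(oracle[15:30])
        assert interior == {4: 6, 7: 2, 11: 2, 15: 5}
        got = [p.period for p in md_series(track_from_types(types))]
        assert got == oracle

    @pytest.mark.parametrize(
        "unit,expected_sum", [(UNIT_15MER, 135), (UNIT_20MER, 380)]
    )
    def test_md_sum_rule(self, unit, expected_sum):
        """Interior-copy MD periods sum to n x tau (15mer: 135, 20mer: 380)."""
        n = len(unit)
        types = _flat([unit] * 6)
        oracle = brute_md_periods(types)
        assert sum(oracle[2 * n : 3 * n]) == expected_sum
        got = [p.period for p in md_series(track_from_types(types))]
        assert sum(got[2 * n : 3 * n]) == expected_sum
        tau = len(set(unit))
        assert expected_sum == n * tau


class TestMonomerSpectrum:
    def test_empty(self):
        assert monomer_grm_spectrum([]) == {}

    @pytest.mark.parametrize(
        "unit,expected",
        [(UNIT_15MER, {4, 7, 11, 15}), (UNIT_20MER, {5, 15, 20}), (UNIT_18MER, {18})],
    )
    def test_tandem_array_period_support(self, unit, expected):
        track = track_from_types(_flat([unit] * 8))
        spec = monomer_grm_spectrum(md_series(track))
        assert set(spec) == expected


class TestDetectArrays:
    def test_two_arrays_split_at_break(self):
        types = _flat([UNIT_15MER] * 10) + [t + 100 for t in _flat([UNIT_20MER] * 10)]
        track = track_from_types(types)
        track.breaks = [150]
        regions = detect_hor_arrays(md_series(track), breaks=track.breaks)
        assert [r.primary_period for r in regions] == [15, 20]

    def test_cascading_15mer_region_with_subfragments(self):
        track = track_from_types(_flat([UNIT_15MER] * 10))
        (region,) = detect_hor_arrays(md_series(track))
        assert region.primary_period == 15
        assert region.subfragment_periods == {4, 7, 11}
        assert region.secondary_periods == set()

    def test_random_type_order_yields_no_region(self):
        rng = np.random.default_rng(23)
        types = rng.integers(0, 50, size=400).tolist()
        assert detect_hor_arrays(md_series(track_from_types(types))) == []

    def test_short_span_filtered(self):
        track = track_from_types(_flat([UNIT_15MER] * 3))
        assert detect_hor_arrays(md_series(track), min_region_monomers=50) == []


class TestCanonicalUnit:
    def test_recovers_planted_unit(self):
        track = track_from_types(_flat([UNIT_20MER] * 12))
        (region,) = detect_hor_arrays(md_series(track))
        units = infer_canonical_unit(track, region)
        assert units == (UNIT_20MER,)

    def test_interspersed_returns_both_units(self):
        schemes = [UNIT_26MER] * 4 + [UNIT_25MER] + [UNIT_26MER] * 3 + \
            [UNIT_25MER] * 2 + [UNIT_26MER] * 7 + [UNIT_25MER] * 20
        track = track_from_types(_flat(schemes))
        (region,) = detect_hor_arrays(md_series(track))
        units = infer_canonical_unit(track, region)
        assert sorted(len(u) for u in units) == [25, 26]
        assert set(map(tuple, units)) == {UNIT_25MER, UNIT_26MER}

    def test_region_too_short_raises(self):
        track = track_from_types(_flat([UNIT_15MER] * 10))
        (region,) = detect_hor_arrays(md_series(track))
        region.last = region.first + 20  # fewer than 2n monomers
        with pytest.raises(ValueError):
            infer_canonical_unit(track, region)


class TestSegmentCopies:
    def _copies(self, schemes):
        track = track_from_types(_flat(schemes))
        (region,) = detect_hor_arrays(md_series(track))
        units = infer_canonical_unit(track, region)
        return segment_copies(track, region, units)

    def test_pure_canonical_array(self):
        copies = self._copies([UNIT_15MER] * 10)
        assert len(copies) == 10
        assert all(c.label == "canonical" for c in copies)
        assert all(len(c) == 15 for c in copies)

    def test_every_monomer_in_exactly_one_copy(self):
        schemes = [UNIT_15MER] * 4 + [UNIT_15MER[4:]] + [UNIT_15MER] * 3
        copies = self._copies(schemes)
        covered = [i for c in copies for i in c.enumeration_indices]
        assert covered == list(range(1, len(covered) + 1))

    def test_shortest_variant_signature_t1_to_t4(self):
        """A planted first-row quadruplet is reported as a variant (t1,t2,t3,t4)."""
        schemes = [UNIT_15MER] * 4 + [UNIT_15MER[:4]] + [UNIT_15MER] * 4
        copies = self._copies(schemes)
        variants = [c for c in copies if c.label == "variant"]
        assert len(variants) == 1
        assert variants[0].signature == (1, 2, 3, 4)

    def test_row_deleted_variant_counted_once(self):
        schemes = [UNIT_15MER] * 3 + [UNIT_15MER[4:]] * 2 + [UNIT_15MER] * 3
        copies = self._copies(schemes)
        assert len(copies) == 8
        assert sum(c.label == "variant" for c in copies) == 2


class TestCascadingScheme:
    def test_canonical_15mer_layout(self):
        scheme = build_scheme(UNIT_15MER)
        assert (scheme.n, scheme.n_types, scheme.n_rows) == (15, 9, 4)
        assert scheme.column_occupancy()[:4] == [2, 3, 3, 2]

    def test_willard_18mer_single_row(self):
        scheme = build_scheme(UNIT_18MER)
        assert (scheme.n, scheme.n_types, scheme.n_rows) == (18, 18, 1)

    def test_canonical_20mer_two_rows_repeated_type_aligned(self):
        scheme = build_scheme(UNIT_20MER)
        assert (scheme.n, scheme.n_types, scheme.n_rows) == (20, 19, 2)
        occ = scheme.column_occupancy()
        assert occ.count(2) == 1 and occ[8] == 2  # only t9 holds two monomers

    def test_rows_strictly_increasing_columns(self):
        for unit in (UNIT_15MER, UNIT_20MER, UNIT_25MER):
            for row in build_scheme(unit).rows:
                cols = [c for c, _ in row]
                assert cols == sorted(set(cols))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=8), min_size=1, max_size=40))
    def test_flatten_round_trip(self, seq):
        scheme = build_scheme(seq)
        assert scheme.flatten() == seq


class TestSubfragmentAndSecondary:
    def _region(self, schemes):
        track = track_from_types(_flat(schemes))
        md = md_series(track)
        (region,) = detect_hor_arrays(md, breaks=[])
        return md, region

    @pytest.mark.parametrize(
        "unit,expected",
        [(UNIT_15MER, {4, 7, 11}), (UNIT_20MER, {5, 15}), (UNIT_18MER, set())],
    )
    def test_subfragment_sets(self, unit, expected):
        md, region = self._region([unit] * 10)
        assert subfragment_periods(md, region) == expected

    def test_subfragments_shrink_as_threshold_rises(self):
        md, region = self._region([UNIT_15MER] * 10)
        prev = subfragment_periods(md, region, min_copy_fraction=0.1)
        for frac in (0.5, 1.5, 3.0):
            cur = subfragment_periods(md, region, min_copy_fraction=frac)
            assert cur <= prev
            prev = cur

    def test_doublets_create_tertiary_period_34(self):
        md, region = self._region(doublet_25mer_schemes(48))
        assert region.primary_period == 25
        assert 34 in secondary_periods(md, region)

    def test_no_doublets_no_secondary(self):
        md, region = self._region([UNIT_25MER] * 48)
        assert secondary_periods(md, region) == set()

    def test_pure_cascading_array_no_secondary(self):
        md, region = self._region([UNIT_15MER] * 10)
        assert secondary_periods(md, region) == set()


class TestCompareUnits:
    def test_25_26mer_share_22_of_29(self):
        cmp = compare_units(UNIT_25MER, UNIT_26MER)
        assert cmp.shared == 22
        assert cmp.unique_to_a == frozenset({10, 15, 27})
        assert cmp.unique_to_b == frozenset({11, 16, 17, 28})
        assert cmp.shared + len(cmp.unique_to_a) + len(cmp.unique_to_b) == 29

    def test_identical_units(self):
        cmp = compare_units(UNIT_15MER, UNIT_15MER)
        assert cmp.shared == 9
        assert not cmp.unique_to_a and not cmp.unique_to_b

    def test_disjoint_units(self):
        cmp = compare_units((1, 2, 3), (4, 5, 6))
        assert cmp.shared == 0


class TestDoubletStructure:
    def test_doublet_member_lengths_sum_to_34(self):
        assert len(DOUBLET_FIRST) == 12
        assert len(DOUBLET_SECOND) == 22
        assert len(DOUBLET_FIRST) + len(DOUBLET_SECOND) == 34
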