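"""Divergence metric, clustering behaviour and consensus building."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cascadehor.families import (
    build_families,
    cluster_families,
    consensus,
    cyclic_divergence,
    divergence,
    divergence_matrix,
    merge_rotated_families,
    MonomerFamily,
)
from cascadehor.simulate import make_family_library, mutate

from helpers import dp_divergence


def _rand(n, rng):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestDivergence:
    def test_identical_strings_zero(self):
        s = "ACGT" * 43
        assert divergence(s, s) == 0.0

    def test_single_substitution(self):
        rng = np.random.default_rng(0)
        a = _rand(171, rng)
        b = a[:50] + ("A" if a[50] != "A" else "C") + a[51:]
        assert divergence(a, b) == pytest.approx(100.0 / 171)

    @pytest.mark.parametrize("pair", [("ACGT", "TGCA"), ("ACGTACGT", "ACGT"), ("AAAA", "TTTT")])
    def test_agrees_with_dp_oracle_and_symmetric(self, pair):
        a, b = pair
        assert divergence(a, b) == pytest.approx(dp_divergence(a, b))
        assert divergence(a, b) == pytest.approx(divergence(b, a))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            divergence("", "ACGT")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=40),
        st.text(alphabet="ACGT", min_size=1, max_size=40),
    )
    def test_matches_dp_oracle_property(self, a, b):
        assert abs(divergence(a, b) - dp_divergence(a, b)) < 1e-9

    def test_random_pairs_match_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            a = _rand(int(rng.integers(20, 60)), rng)
            b = _rand(int(rng.integers(20, 60)), rng)
            assert abs(divergence(a, b) - dp_divergence(a, b)) < 1e-9


class TestDivergenceMatrix:
    def test_single_monomer(self):
        mat = divergence_matrix(["ACGTACGT"])
        assert mat.shape == (1, 1) and mat[0, 0] == 0.0

    def test_symmetric_and_block_structured(self):
        lib = make_family_library(2, seed=3)
        rng = np.random.default_rng(3)
        monomers = [mutate(lib.consensi[i], 0.01, rng) for i in (0, 0, 0, 1, 1, 1)]
        mat = divergence_matrix(monomers)
        assert (mat == mat.T).all()
        assert (np.diag(mat) == 0).all()
        assert mat[:3, :3].max() < 5.0 and mat[3:, 3:].max() < 5.0
        assert mat[:3, 3:].min() >= 20.0

    def test_cap_saturates_distant_pairs_only(self):
        lib = make_family_library(2, seed=3)
        mat = divergence_matrix(list(lib.consensi), cap=15.0)
        assert mat[0, 1] == 100.0


class TestClustering:
    def test_all_close_single_family(self):
        mat = np.full((4, 4), 2.0)
        np.fill_diagonal(mat, 0.0)
        assert cluster_families(mat) == [0, 0, 0, 0]

    def test_well_separated_blocks(self):
        mat = np.array(
            [[0, 2, 25, 25], [2, 0, 25, 25], [25, 25, 0, 3], [25, 25, 3, 0]], dtype=float
        )
        assert cluster_families(mat) == [0, 0, 1, 1]

    def test_chain_case_average_linkage(self):
        """a-b=4, b-c=4, a-c=8: a,b merge at 4; c joins at mean(8,4)=6 > 5,
        so the partition is {a,b},{c}."""
        mat = np.array([[0, 4, 8], [4, 0, 4], [8, 4, 0]], dtype=float)
        assert cluster_families(mat, threshold=5.0, method="average") == [0, 0, 1]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(1, 30, size=(8, 8))
        mat = (base + base.T) / 2
        np.fill_diagonal(mat, 0.0)
        prev = cluster_families(mat, threshold=2.0)
        for t in (4.0, 8.0, 16.0, 31.0):
            cur = cluster_families(mat, threshold=t)
            # coarsening: members sharing a family at low t still share at high t
            for i in range(8):
                for j in range(8):
                    if prev[i] == prev[j]:
                        assert cur[i] == cur[j]
            prev = cur

    def test_partition_invariant_under_permutation(self):
        lib = make_family_library(3, seed=9)
        rng = np.random.default_rng(9)
        monomers = [mutate(lib.consensi[i % 3], 0.02, rng) for i in range(12)]
        _, labels = build_families(monomers)
        order = rng.permutation(12)
        _, labels_perm = build_families([monomers[i] for i in order])
        for a in range(12):
            for b in range(12):
                same = labels[order[a]] == labels[order[b]]
                assert same == (labels_perm[a] == labels_perm[b])


class TestConsensus:
    def test_single_member_verbatim(self):
        assert consensus(["ACGTTT"]) == "ACGTTT"

    def test_majority_outvotes_single_substitution(self):
        rng = np.random.default_rng(1)
        base = _rand(171, rng)
        mutant = base[:80] + ("G" if base[80] != "G" else "T") + base[81:]
        assert consensus([base, base, mutant]) == base

    def test_recovers_planted_consensus_from_noisy_members(self):
        lib = make_family_library(1, seed=2)
        rng = np.random.default_rng(2)
        members = [mutate(lib.consensi[0], 0.02, rng) for _ in range(5)]
        assert divergence(consensus(members), lib.consensi[0]) < 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consensus([])


class TestRotationMerge:
    def test_rotated_duplicate_dropped(self):
        lib = make_family_library(2, seed=4)
        cons = lib.consensi[0]
        rotated = cons[40:] + cons[:40]
        fams = [
            MonomerFamily(0, cons, 50),
            MonomerFamily(1, rotated, 5),
            MonomerFamily(2, lib.consensi[1], 40),
        ]
        kept, merged = merge_rotated_families(fams)
        assert [f.family_id for f in kept] == [0, 2]
        assert merged == {1: 0}

    def test_cyclic_divergence_zero_for_rotation(self):
        s = "ACGTTGCAAC" * 17
        assert cyclic_divergence(s[7:] + s[:7], s) == 0.0
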