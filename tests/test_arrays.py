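"""Elementary array moves: founder layouts, Pólya replication, shuffling, division."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare

from mitohet.arrays import (
    allele_fraction,
    as_array,
    divide,
    init_founder,
    replicate_to_capacity,
    shuffle,
    to_string,
)


def polya_distribution(count0: int, count1: int, target: int) -> dict[int, float]:
    """Exact law of the final allele-1 count under Pólya-urn growth.

    Independent oracle: recursively enumerates every pick sequence of the
    urn process (each existing molecule equally likely to template the
    next copy) and accumulates path probabilities.
    """
    dist: dict[int, float] = {}

    def recurse(c0: int, c1: int, prob: float) -> None:
        n = c0 + c1
        if n == target:
            dist[c1] = dist.get(c1, 0.0) + prob
            return
        if c0:
            recurse(c0 + 1, c1, prob * c0 / n)
        if c1:
            recurse(c0, c1 + 1, prob * c1 / n)

    recurse(count0, count1, 1.0)
    return dist


class TestFounder:
    @pytest.mark.parametrize(
        "n, pattern, frac, expected",
        [
            (32, "mixed", 0.5, "01" * 16),
            (2, "mixed", 0.5, "01"),
            (10, "non_mixed", 0.5, "0000011111"),
            (10, "semi_mixed", 0.5, "0011100011"),
            (4, "mixed", 0.25, "0001"),
        ],
    )
    def test_named_layouts(self, n, pattern, frac, expected):
        assert to_string(init_founder(n, pattern, frac)) == expected

    def test_explicit_sequence_passthrough(self):
        assert to_string(init_founder(6, "001101")) == "001101"
        assert to_string(init_founder(4, [1, 0, 1, 0])) == "1010"

    @pytest.mark.parametrize("pattern", ["mixed", "semi_mixed", "non_mixed"])
    @pytest.mark.parametrize("n, frac", [(32, 0.5), (33, 0.4), (26, 0.3), (90, 0.5)])
    def test_composition_matches_rounded_fraction(self, pattern, n, frac):
        arr = init_founder(n, pattern, frac)
        assert len(arr) == n
        assert arr.sum() == round(n * frac)

    def test_degenerate_mixed_is_permitted_but_logged(self, caplog):
        with caplog.at_level("WARNING", logger="mitohet.arrays"):
            arr = init_founder(8, "mixed", 0.0)
        assert arr.sum() == 0
        assert any("degenerate" in r.message for r in caplog.records)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            init_founder(1, "mixed", 0.5)
        with pytest.raises(ValueError):
            init_founder(8, "mixed", 1.5)
        with pytest.raises(ValueError):
            as_array("0120")


class TestReplicateToCapacity:
    def test_homoplasmy_is_absorbing(self, rng):
        out = replicate_to_capacity(np.zeros(14, dtype=np.uint8), 32, rng)
        assert len(out) == 32 and out.sum() == 0

    def test_at_capacity_is_identity(self, rng):
        arr = as_array("01")
        assert to_string(replicate_to_capacity(arr, 2, rng)) == "01"

    def test_above_capacity_rejected(self, rng):
        with pytest.raises(ValueError, match="depletion"):
            replicate_to_capacity(np.zeros(5, dtype=np.uint8), 4, rng)

    def test_polya_uniformity_oracle(self, rng):
        """Growing '01' to 4 copies gives allele-1 counts uniform on {1,2,3}.

        The expected law comes from exact enumeration of the urn process;
        the empirical frequencies must match it (chi-square).
        """
        oracle = polya_distribution(1, 1, 4)
        assert oracle == pytest.approx({1: 1 / 3, 2: 1 / 3, 3: 1 / 3})
        draws = 30_000
        counts = np.zeros(5, dtype=int)
        for _ in range(draws):
            out = replicate_to_capacity(as_array("01"), 4, rng)
            counts[out.sum()] += 1
        assert counts[0] == counts[4] == 0  # both variants survive
        p = chisquare(counts[1:4], draws * np.array([oracle[k] for k in (1, 2, 3)])).pvalue
        assert p > 0.001

    def test_insertion_adjacent_to_template(self, rng):
        # from '01', one insertion yields '001' or '011', never '010' or '101'
        seen = set()
        for _ in range(200):
            seen.add(to_string(replicate_to_capacity(as_array("01"), 3, rng)))
        assert seen == {"001", "011"}


class TestShuffle:
    def test_single_fragment_is_identity(self, rng):
        arr = as_array("0011010011")
        assert to_string(shuffle(arr, 1, rng)) == "0011010011"

    def test_singleton_fragments_give_uniform_permutation(self, rng):
        """nspl = length reduces shuffling to a uniform permutation of copies."""
        strings = {"0011", "0101", "0110", "1001", "1010", "1100"}
        tally = {s: 0 for s in strings}
        draws = 30_000
        for _ in range(draws):
            tally[to_string(shuffle(as_array("0011"), 4, rng))] += 1
        p = chisquare(list(tally.values())).pvalue
        assert p > 0.001

    def test_two_fragments_of_two_copies(self, rng):
        outs = {to_string(shuffle(as_array("01"), 2, rng)) for _ in range(200)}
        assert outs == {"01", "10"}

    def test_too_many_fragments_rejected(self, rng):
        with pytest.raises(ValueError):
            shuffle(as_array("0101"), 5, rng)

    @settings(max_examples=50, derandomize=True)
    @given(
        bits=st.lists(st.integers(0, 1), min_size=2, max_size=40),
        nspl=st.integers(1, 40),
        seed=st.integers(0, 10**6),
    )
    def test_conserves_allele_multiset(self, bits, nspl, seed):
        arr = np.array(bits, dtype=np.uint8)
        nspl = min(nspl, len(arr))
        out = shuffle(arr, nspl, np.random.default_rng(seed))
        assert len(out) == len(arr) and out.sum() == arr.sum()


class TestDivide:
    def test_fixed_end_split(self):
        mother, daughter = divide(as_array("00001111"), 3)
        assert to_string(daughter) == "000" and to_string(mother) == "01111"

    @pytest.mark.parametrize("n, ndau", [(32, 16), (56, 28), (90, 45)])
    def test_half_cap_split_sizes(self, n, ndau):
        mother, daughter = divide(np.zeros(n, dtype=np.uint8), ndau)
        assert len(daughter) == ndau and len(mother) == n - ndau

    def test_cap_enforced(self):
        with pytest.raises(ValueError, match="half the copy number"):
            divide(np.zeros(32, dtype=np.uint8), 17)
        with pytest.raises(ValueError):
            divide(np.zeros(8, dtype=np.uint8), 0)

    @settings(max_examples=50, derandomize=True)
    @given(bits=st.lists(st.integers(0, 1), min_size=2, max_size=60), ndau=st.integers(1, 30))
    def test_concatenation_reconstructs_input(self, bits, ndau):
        arr = np.array(bits, dtype=np.uint8)
        ndau = min(ndau, len(arr) // 2)
        mother, daughter = divide(arr, ndau)
        assert to_string(daughter) + to_string(mother) == to_string(arr)


class TestAlleleFraction:
    @pytest.mark.parametrize(
        "s, f", [("0101", 0.5), ("1111", 1.0), ("0001", 0.25), ("0", 0.0)]
    )
    def test_examples(self, s, f):
        assert allele_fraction(as_array(s)) == f
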