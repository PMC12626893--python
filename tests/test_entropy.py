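import itertools
import math

import numpy as np
import pytest
from scipy import stats

from helixcharge import (
    Alignment,
    column_entropy,
    column_profile,
    compact_letter_display,
    compare_entropy_groups,
    entropy_profile,
    tukey_hsd,
)
from helixcharge.entropy import ColumnProfile, pairwise_bonferroni


class TestColumnEntropy:
    def test_monomorphic_column_is_zero(self):
        assert column_entropy(column_profile("AAAA")) == 0.0

    def test_half_quarter_quarter_is_one_and_a_half_bits(self):
        assert column_entropy(ColumnProfile({"A": 2, "C": 1, "D": 1})) == pytest.approx(1.5)

    def test_uniform_is_log2_twenty(self):
        prof = ColumnProfile({a: 1 for a in "ACDEFGHIKLMNPQRSTVWY"})
        assert column_entropy(prof) == pytest.approx(math.log2(20))

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError, match="empty column"):
            column_entropy(column_profile("--X"))

    def test_gaps_and_x_excluded_from_counts(self):
        assert column_profile("AA--XX").n_eff == 2

    def test_permutation_invariance(self):
        # relabeling residue identities leaves H unchanged
        base = {"A": 5, "C": 3, "D": 2}
        relabeled = {"W": 5, "Y": 3, "K": 2}
        assert column_entropy(ColumnProfile(base)) == pytest.approx(
            column_entropy(ColumnProfile(relabeled))
        )

    def test_bounds_on_random_columns(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            counts = rng.integers(0, 10, size=20)
            if counts.sum() == 0:
                continue
            prof = ColumnProfile(
                {a: int(c) for a, c in zip("ACDEFGHIKLMNPQRSTVWY", counts) if c}
            )
            h = column_entropy(prof)
            assert 0.0 <= h <= math.log2(20) + 1e-12


class TestProfiles:
    def test_identical_rows_zero_everywhere(self):
        aln = Alignment(ids=list("abcd"), rows=["MKR"] * 4)
        prof = entropy_profile(aln, family="I", region="nterm")
        assert prof.H == [0.0, 0.0, 0.0]

    def test_single_row_all_skipped(self):
        aln = Alignment(ids=["a"], rows=["MKR"])
        with pytest.warns(UserWarning, match="no usable columns"):
            prof = entropy_profile(aln, family="I", region="nterm")
        assert prof.H == [] and prof.n_skipped == 3

    def test_family_two_nterm_more_diverse(self, default_dataset):
        # the generator gives family II a higher N-terminal substitution rate
        ds = default_dataset
        lo, hi = ds.nterm_cols
        blocks = {}
        for fam in ("I", "II"):
            ids = [i for i in ds.alignment.ids if ds.families[i] == fam]
            rows = [ds.alignment.row(i)[lo:hi] for i in ids]
            blocks[fam] = Alignment(ids=ids, rows=rows)
        h1 = entropy_profile(blocks["I"], family="I", region="nterm")
        h2 = entropy_profile(blocks["II"], family="II", region="nterm")
        assert np.mean(h2.H) > np.mean(h1.H)


class TestTukey:
    def test_matches_scipy_tukey_hsd(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(i * 0.5, 1, 25) for i, k in enumerate("abc")}
        ours = tukey_hsd(groups)
        ref = stats.tukey_hsd(*groups.values())
        for (i, a), (j, b) in itertools.combinations(enumerate("abc"), 2):
            assert ours[(a, b)] == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_well_separated_group_detected(self):
        # permutation-style oracle case: means 0, 0, 10; only pairs with the
        # shifted group are significant
        rng = np.random.default_rng(4)
        groups = {
            "g1": rng.normal(0, 1, 50),
            "g2": rng.normal(0, 1, 50),
            "g3": rng.normal(10, 1, 50),
        }
        p = tukey_hsd(groups)
        assert p[("g1", "g3")] < 0.01 and p[("g2", "g3")] < 0.01
        assert p[("g1", "g2")] > 0.01

    def test_identical_observations_give_p_one(self):
        groups = {"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]}
        assert tukey_hsd(groups)[("a", "b")] == 1.0

    def test_zero_variance_unequal_means_give_p_zero(self):
        groups = {"a": [1.0, 1.0], "b": [2.0, 2.0]}
        assert tukey_hsd(groups)[("a", "b")] == 0.0

    def test_monotone_in_mean_difference(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 30)
        ps = []
        for shift in (0.1, 0.5, 1.0, 2.0):
            p = tukey_hsd({"a": base, "b": base + shift})
            ps.append(p[("a", "b")])
        assert ps == sorted(ps, reverse=True)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": [1.0], "b": [1.0, 2.0]})


class TestCld:
    @staticmethod
    def _p(groups, sig_pairs):
        p = {}
        for a, b in itertools.combinations(groups, 2):
            val = 0.001 if (a, b) in sig_pairs or (b, a) in sig_pairs else 0.5
            p[(a, b)] = p[(b, a)] = val
        return p

    def test_no_significant_pairs_share_one_letter(self):
        letters = compact_letter_display(list("abc"), self._p("abc", set()), 0.05)
        assert len({v for v in letters.values()}) == 1

    def test_all_significant_pairs_distinct(self):
        sig = set(itertools.combinations("abc", 2))
        letters = compact_letter_display(list("abc"), self._p("abc", sig), 0.05)
        assert all(
            not set(letters[a]) & set(letters[b])
            for a, b in itertools.combinations("abc", 2)
        )

    def test_chain_pattern(self):
        # only (1,3) significant: 1 and 3 share nothing, 2 bridges both
        letters = compact_letter_display(
            list("abc"), self._p("abc", {("a", "c")}), 0.05
        )
        assert not set(letters["a"]) & set(letters["c"])
        assert set(letters["b"]) & set(letters["a"])
        assert set(letters["b"]) & set(letters["c"])

    @pytest.mark.parametrize("n_groups", [3, 4])
    def test_sharing_invariant_on_all_patterns(self, n_groups):
        # brute force over every significance pattern; the construction
        # asserts the sharing invariant internally
        groups = [f"g{i}" for i in range(n_groups)]
        pairs = list(itertools.combinations(groups, 2))
        for mask in range(2 ** len(pairs)):
            sig = {p for i, p in enumerate(pairs) if mask >> i & 1}
            letters = compact_letter_display(groups, self._p(groups, sig), 0.05)
            assert all(letters[g] for g in groups)


def test_group_comparison_reports_both_corrections(default_dataset):
    from helixcharge.pipeline import _family_region_alignments
    from helixcharge import entropy_profiles

    ds = default_dataset
    blocks = _family_region_alignments(ds.alignment, ds.families, ds.nterm_cols, 0.75)
    profiles = entropy_profiles(blocks)
    result = compare_entropy_groups(profiles, alpha=0.01)
    assert set(result.letters) == set(result.groups)
    some_pair = (result.groups[0], result.groups[1])
    assert 0 <= result.p_tukey[some_pair] <= 1
    assert 0 <= result.p_bonferroni[some_pair] <= 1
    # N termini are more variable than the conserved internal region
    assert result.means["II:nterm"] > result.means["II:internal"]
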