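"""Shannon uncertainty, gap-penalized information and signature calls."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cladescan.alignment_io import NUCLEOTIDES, LabeledAlignment
from cladescan.conservation import (
    H_MAX,
    average_information,
    call_signature_sites,
    group_difference,
    relative_information,
    score_sites,
    shannon_uncertainty,
    site_profiles,
    total_information,
)


def brute_force_profiles(aln):
    """Independent per-column tally with the full group size as denominator."""
    out = []
    for c in range(aln.n_columns):
        col = {}
        for grp in ("IN", "OUT"):
            members = [s[c] for i, s in zip(aln.ids, aln.seqs) if aln.group_of[i] == grp]
            n = len(members)
            col[grp] = (
                {nt: members.count(nt) / n for nt in NUCLEOTIDES},
                sum(ch not in NUCLEOTIDES for ch in members) / n,
            )
        out.append(col)
    return out


class TestShannonUncertainty:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ((0.25, 0.25, 0.25, 0.25), 2.0),
            ((1.0, 0.0, 0.0, 0.0), 0.0),
            ((0.5, 0.5, 0.0, 0.0), 1.0),
        ],
    )
    def test_reference_values(self, freqs, expected):
        assert shannon_uncertainty(freqs) == pytest.approx(expected, abs=1e-12)

    def test_gap_mass_contributes_nothing(self):
        """Frequencies are not renormalized: (0.5, 0.5·gap-free) keeps H of the
        nucleotide masses only."""
        h = shannon_uncertainty((0.4, 0.4, 0.0, 0.0))  # 0.2 gap mass
        expected = -2 * 0.4 * math.log2(0.4)
        assert h == pytest.approx(expected)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            shannon_uncertainty((-0.1, 0.5, 0.3, 0.3))
        with pytest.raises(ValueError):
            shannon_uncertainty((0.5, 0.5, 0.5, 0.5))

    @given(
        st.lists(st.floats(0.001, 1.0), min_size=4, max_size=4).map(
            lambda v: tuple(x / sum(v) for x in v)
        )
    )
    def test_permutation_invariant_and_bounded(self, freqs):
        """H is symmetric in the four frequencies, within [0, 2] bits, and
        attains 2 bits only at the uniform distribution."""
        href = shannon_uncertainty(freqs)
        assert 0.0 <= href <= H_MAX + 1e-12
        for perm in itertools.permutations(freqs):
            assert shannon_uncertainty(perm) == pytest.approx(href)
        if abs(href - H_MAX) < 1e-12:
            assert all(f == pytest.approx(0.25) for f in freqs)


class TestTotalInformation:
    @pytest.mark.parametrize(
        "h,gap,expected",
        [(0.0, 0.0, 1.0), (2.0, 0.0, 0.0), (1.0, 0.25, 0.375)],
    )
    def test_reference_values(self, h, gap, expected):
        assert total_information(h, gap) == pytest.approx(expected)

    @given(st.floats(0.0, 2.0), st.floats(0.0, 1.0))
    def test_bounded_and_monotone(self, h, gap):
        t = total_information(h, gap)
        assert 0.0 <= t <= 1.0
        # non-increasing in H and in gap fraction
        assert total_information(min(h + 0.1, 2.0), gap) <= t + 1e-12
        assert total_information(h, min(gap + 0.1, 1.0)) <= t + 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            total_information(2.5, 0.0)
        with pytest.raises(ValueError):
            total_information(1.0, 1.5)


class TestNormalization:
    def test_average_matches_independent_sum(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 1, 1000)
        assert average_information(vals) == pytest.approx(vals.sum() / 1000, abs=1e-12)

    def test_empty_average_rejected(self):
        with pytest.raises(ValueError):
            average_information([])

    @pytest.mark.parametrize(
        "t,t_avg,expected", [(0.6, 0.6, 1.0), (0.0, 0.5, 0.0), (0.9, 0.6, 1.5)]
    )
    def test_relative_information_ratio(self, t, t_avg, expected):
        assert relative_information(t, t_avg) == pytest.approx(expected)

    def test_zero_group_information_rejected(self):
        with pytest.raises(ValueError, match="no information"):
            relative_information(0.5, 0.0)

    def test_difference_sign_convention(self):
        """D > 0 where the in-group is less conserved than the out-group."""
        d = group_difference([0.2, 1.0, 1.0], [1.0, 1.0, 0.4])
        assert d[0] > 0  # variable in IN, conserved in OUT
        assert d[1] == 0
        assert d[2] < 0
        with pytest.raises(ValueError, match="mismatched"):
            group_difference([1.0], [1.0, 2.0])


class TestSiteProfiles:
    def test_counts_with_group_size_denominator(self):
        ids = ["i1", "i2", "i3", "i4", "o1", "o2", "o3", "o4"]
        seqs = ["A", "A", "-", "G", "G", "G", "G", "G"]
        groups = {i: ("IN" if i.startswith("i") else "OUT") for i in ids}
        (p,) = site_profiles(LabeledAlignment(ids, seqs, groups))
        assert p.freq_in == pytest.approx({"A": 0.5, "C": 0.0, "G": 0.25, "U": 0.0})
        assert p.gap_in == pytest.approx(0.25)
        assert p.freq_out["G"] == 1.0 and p.gap_out == 0.0

    def test_empty_group_rejected(self):
        aln = LabeledAlignment(["a", "b"], ["AC", "GU"], {"a": "IN", "b": "IN"})
        with pytest.raises(ValueError, match="out-group is empty"):
            site_profiles(aln)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(11)
        chars = np.array(list("ACGU-"))
        mat = chars[rng.integers(0, 5, size=(20, 50))]
        ids = [f"s{k}" for k in range(20)]
        groups = {i: ("IN" if k < 10 else "OUT") for k, i in enumerate(ids)}
        aln = LabeledAlignment(ids, ["".join(r) for r in mat], groups)
        profiles = site_profiles(aln)
        oracle = brute_force_profiles(aln)
        for p, o in zip(profiles, oracle):
            assert p.freq_in == pytest.approx(o["IN"][0])
            assert p.gap_in == pytest.approx(o["IN"][1])
            assert p.freq_out == pytest.approx(o["OUT"][0])
            assert p.gap_out == pytest.approx(o["OUT"][1])
            # frequencies + gap sum to one per group
            assert sum(p.freq_in.values()) + p.gap_in == pytest.approx(1.0)


class TestSignatureCalls:
    def test_fixed_difference_called(self):
        ids = ["i1", "i2", "o1", "o2"]
        aln = LabeledAlignment(
            ids, ["A", "A", "G", "G"], {"i1": "IN", "i2": "IN", "o1": "OUT", "o2": "OUT"}
        )
        calls = call_signature_sites(site_profiles(aln))
        assert len(calls) == 1
        assert (calls[0].nucleotide, calls[0].freq_in, calls[0].freq_out) == ("A", 1.0, 0.0)

    def test_shared_fixation_not_called(self):
        ids = ["i1", "i2", "o1", "o2"]
        aln = LabeledAlignment(
            ids, ["A", "A", "A", "A"], {"i1": "IN", "i2": "IN", "o1": "OUT", "o2": "OUT"}
        )
        assert call_signature_sites(site_profiles(aln)) == []

    def test_inclusive_boundary(self):
        """9/10 + one gap in-group (freq 0.9) and 1/10 out-group (0.1) both sit
        exactly on the thresholds and the call is emitted."""
        ids = [f"i{k}" for k in range(10)] + [f"o{k}" for k in range(10)]
        in_seqs = ["A"] * 9 + ["-"]
        out_seqs = ["A"] + ["G"] * 9
        groups = {i: ("IN" if i.startswith("i") else "OUT") for i in ids}
        aln = LabeledAlignment(ids, in_seqs + out_seqs, groups)
        calls = call_signature_sites(site_profiles(aln))
        assert [(c.nucleotide, c.freq_in, c.freq_out) for c in calls] == [("A", 0.9, 0.1)]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan(self, seed):
        """Calls equal a brute-force scan over all (column, nucleotide) pairs."""
        rng = np.random.default_rng(seed)
        chars = np.array(list("ACGU-"))
        n, L = int(rng.integers(4, 21)), int(rng.integers(5, 101))
        n_in = int(rng.integers(2, n - 1))
        mat = chars[rng.integers(0, 5, size=(n, L))]
        ids = [f"s{k}" for k in range(n)]
        groups = {i: ("IN" if k < n_in else "OUT") for k, i in enumerate(ids)}
        aln = LabeledAlignment(ids, ["".join(r) for r in mat], groups)
        calls = call_signature_sites(site_profiles(aln))
        expected = []
        for c in range(L):
            in_col = [s[c] for k, s in enumerate(aln.seqs) if k < n_in]
            out_col = [s[c] for k, s in enumerate(aln.seqs) if k >= n_in]
            for nt in NUCLEOTIDES:
                fi = in_col.count(nt) / len(in_col)
                fo = out_col.count(nt) / len(out_col)
                if fi >= 0.90 and fo <= 0.10:
                    expected.append((c + 1, nt))
        assert [(c.column, c.nucleotide) for c in calls] == expected


class TestScoreSites:
    def test_t_avg_is_mean_of_t(self, toy_alignment):
        table = score_sites(toy_alignment)
        assert table.t_avg_in == pytest.approx(table.scores["T_in"].mean())
        assert table.t_avg_out == pytest.approx(table.scores["T_out"].mean())
        assert np.allclose(
            table.scores["D"],
            table.scores["R_out"] - table.scores["R_in"],
        )

    def test_original_column_indices_preserved(self, toy_alignment):
        table = score_sites(toy_alignment.subset_columns([1, 3, 4]), [1, 3, 4])
        assert table.scores["column"].tolist() == [1, 3, 4]

    def test_planted_fast_sites_rank_high(self, survey_bundle):
        """Columns simulated with elevated in-group substitution separate from
        background in the difference score."""
        from cladescan.alignment_io import filter_gap_columns, read_labeled_alignment

        aln = read_labeled_alignment(survey_bundle.alignment, survey_bundle.labels)
        filt = filter_gap_columns(aln)
        table = score_sites(filt.filtered, filt.kept_columns)
        fast = survey_bundle.truth.fast_columns
        in_fast = table.scores["column"].isin(fast)
        assert table.scores.loc[in_fast, "D"].mean() > table.scores.loc[~in_fast, "D"].mean()
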