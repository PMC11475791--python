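"""Summary percentages and the paired nonparametric statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bovcdr3 import (
    PairedDesign,
    mean_sem,
    pearson_correlation,
    spearman_correlation,
    summarize,
    summarize_gene_usage,
    wilcoxon_signed_rank_exact,
)
from bovcdr3.extraction import Cdr3Call, Cdr3Class
from bovcdr3.filtering import StageCounts
from bovcdr3.seq_core import MatchResult
from bovcdr3.stats import round_half_up
from bovcdr3.study_data import paired_design


def fake_call(i, aa_len, productive=True, rejected=False):
    nt = 3 * aa_len
    return Cdr3Call(
        read_id=f"r{i}", cdr3_nt="A" * nt, nt_len=nt, aa_len=aa_len,
        in_frame=True, productive=productive and not rejected,
        cdr3_class=(
            Cdr3Class.REJECTED if rejected
            else Cdr3Class.SHORT if aa_len <= 10
            else Cdr3Class.ULTRALONG if aa_len >= 40
            else Cdr3Class.MEDIUM
        ),
        pre_match=MatchResult(0, 1, 0), post_match=MatchResult(1, 2, 0),
    )


def counts_for(n):
    return StageCounts(raw=n, cleaned=n, step1_forward_primer=n,
                       step2_isotype_motif=n, merged_unique=n)


class TestSummarize:
    def test_ten_ultralong_among_hundred(self):
        calls = [fake_call(i, 50) for i in range(10)] + [
            fake_call(10 + i, 20) for i in range(90)
        ]
        s = summarize("s", calls, counts_for(100))
        assert s.pct_ultralong_dna.rounded == 10.00
        assert s.pct_ultralong_dna.denominator == 100

    def test_zero_ultralong_is_zero_percent_with_denominator(self):
        calls = [fake_call(i, 20) for i in range(50)]
        s = summarize("s", calls, counts_for(50))
        assert s.pct_ultralong_dna.rounded == 0.00
        assert s.pct_ultralong_dna.denominator == 50
        assert not s.flags

    def test_zero_denominator_is_flagged_not_silent_zero(self):
        calls = [fake_call(0, 1, rejected=True)]
        s = summarize("s", calls, counts_for(1))
        assert s.pct_ultralong_dna.value is None
        assert s.flags

    def test_rejected_calls_excluded_from_denominator(self):
        calls = [fake_call(0, 50), fake_call(1, 1, rejected=True)]
        s = summarize("s", calls, counts_for(2))
        assert s.pct_ultralong_dna.denominator == 1
        assert s.pct_ultralong_dna.rounded == 100.00


class TestMeanSem:
    @pytest.mark.parametrize(
        "values,mean,sem",
        [
            ((2.23, 4.03, 5.39, 6.70, 5.12, 4.70, 1.38), 4.22, 0.70),
            ((18.03, 6.67, 10.96, 6.96, 11.89, 19.54, 16.79), 12.98, 1.98),
        ],
    )
    def test_reproduces_published_rows(self, values, mean, sem):
        m, s = mean_sem(values)
        assert round_half_up(m) == mean
        assert round_half_up(s) == sem

    def test_constant_vector_has_zero_sem(self):
        m, s = mean_sem([5.0] * 6)
        assert (m, s) == (5.0, 0.0)

    def test_single_value_sem_undefined(self):
        m, s = mean_sem([3.0])
        assert m == 3.0 and s is None


def brute_force_exact_p(diffs):
    """Independent oracle: enumerate sign assignments literally."""
    diffs = [d for d in diffs if d != 0]
    ranks = sps.rankdata([abs(d) for d in diffs])
    w_obs = min(
        sum(r for d, r in zip(diffs, ranks) if d > 0),
        sum(r for d, r in zip(diffs, ranks) if d < 0),
    )
    total = sum(ranks)
    n_le = 0
    for signs in itertools.product([1, -1], repeat=len(diffs)):
        w_plus = sum(r for s, r in zip(signs, ranks) if s > 0)
        if min(w_plus, total - w_plus) <= w_obs + 1e-12:
            n_le += 1
    return n_le / 2 ** len(diffs)


class TestWilcoxonExact:
    def test_igm_pairs_give_six_in_128(self):
        design = paired_design("productive_ultralong", "IgM")
        w, p = wilcoxon_signed_rank_exact(design)
        assert w == 2.0
        assert p == pytest.approx(6 / 128)
        assert p == pytest.approx(brute_force_exact_p(design.differences()))

    def test_matches_scipy_exact_mode(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 10))
            blood = rng.normal(5, 2, n)
            colostrum = blood + rng.normal(0.5, 1.5, n)
            design = PairedDesign(tuple(map(str, range(n))), tuple(blood), tuple(colostrum))
            _, p = wilcoxon_signed_rank_exact(design)
            ref = sps.wilcoxon(colostrum, blood, mode="exact").pvalue
            assert p == pytest.approx(ref)

    def test_single_pair_p_is_one(self):
        design = PairedDesign(("c1",), (1.0,), (2.0,))
        w, p = wilcoxon_signed_rank_exact(design)
        assert p == 1.0

    def test_symmetric_under_side_swap(self):
        d = paired_design("productive_ultralong", "IgG")
        swapped = PairedDesign(d.cow_ids, d.colostrum, d.blood)
        assert wilcoxon_signed_rank_exact(d) == wilcoxon_signed_rank_exact(swapped)

    def test_all_zero_differences_undefined(self):
        design = PairedDesign(("a", "b"), (1.0, 2.0), (1.0, 2.0))
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank_exact(design)

    def test_small_hand_case_all_sign_patterns(self):
        # n=3, distinct ranks: min-rank-sum distribution over 8 assignments
        design = PairedDesign(("a", "b", "c"), (0.0, 0.0, 0.0), (1.0, 2.0, 3.0))
        w, p = wilcoxon_signed_rank_exact(design)
        assert w == 0.0
        assert p == pytest.approx(2 / 8)  # only the two one-sided extremes

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            _, p = wilcoxon_signed_rank_exact(
                PairedDesign(tuple(map(str, range(6))), tuple(x), tuple(y))
            )
            assert 0 < p <= 1


class TestCorrelation:
    def test_published_paired_correlations(self):
        r_igm = pearson_correlation(paired_design("productive_ultralong", "IgM"))
        r_igg = pearson_correlation(paired_design("productive_ultralong", "IgG"))
        assert round_half_up(r_igm) == 0.69
        assert round_half_up(r_igg) == -0.11

    def test_perfect_linear_relation(self):
        x = (1.0, 2.0, 3.0, 4.0)
        y = tuple(2 * v + 1 for v in x)
        assert pearson_correlation(PairedDesign(("a", "b", "c", "d"), x, y)) == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        ids = tuple(map(str, range(8)))
        r1 = pearson_correlation(PairedDesign(ids, tuple(x), tuple(y)))
        r2 = pearson_correlation(PairedDesign(ids, tuple(3 * x - 2), tuple(0.5 * y + 7)))
        assert r1 == pytest.approx(r2)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation(PairedDesign(("a", "b", "c"), (1.0, 1.0, 1.0), (1.0, 2.0, 3.0)))

    def test_spearman_option_exists(self):
        d = paired_design("productive_ultralong", "IgM")
        assert -1 <= spearman_correlation(d) <= 1


class TestGeneUsage:
    def test_toy_percentages(self):
        df = pd.DataFrame({
            "read_id": [f"r{i}" for i in range(10)],
            "sample": ["s1"] * 10,
            "v_gene": ["IGHV1-7"] * 3 + ["IGHV1-10"] * 7,
        })
        out = summarize_gene_usage(df)
        pct = dict(zip(out.gene, out.pct))
        assert pct["IGHV1-7"] == 30.00
        assert pct["IGHV1-10"] == 70.00

    def test_unassigned_excluded_and_counted(self):
        df = pd.DataFrame({
            "read_id": ["a", "b", "c", "d"],
            "sample": ["s1"] * 4,
            "v_gene": ["IGHV1-7", None, "", "IGHV1-7"],
        })
        out = summarize_gene_usage(df)
        assert out.attrs["n_unassigned"] == 2
        assert out.loc[out.gene == "IGHV1-7", "pct"].iloc[0] == 100.00

    def test_empty_table_flagged(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_gene_usage(pd.DataFrame(columns=["read_id", "sample", "v_gene"]))

    def test_listed_percentages_sum_at_most_100(self):
        df = pd.DataFrame({
            "read_id": [f"r{i}" for i in range(8)],
            "sample": ["s1"] * 8,
            "v_gene": ["A", "A", "B", "B", "B", "C", "C", "C"],
        })
        out = summarize_gene_usage(df)
        assert out[out["sample"] == "s1"].pct.sum() <= 100.0 + 1e-9
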