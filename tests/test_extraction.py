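"""Junction location, CDR3 excision, translation, classification."""

import numpy as np
import pytest

from bovcdr3 import (
    AmpliconRead,
    Cdr3Class,
    FilterConfig,
    MatchResult,
    call_cdr3,
    classify_length,
    excise_cdr3,
    extract_cdr3s,
    locate_junction,
    translate,
    translate_window,
)
from bovcdr3.config import POST_CDR3_EXEMPLAR, PRE_CDR3_EXEMPLAR, default_motif_set
from bovcdr3.filtering import rslb_filter
from bovcdr3.simulate import SimConfig, generate

PRE = PRE_CDR3_EXEMPLAR   # ends 2 nt into the C104 codon
POST = POST_CDR3_EXEMPLAR  # opens with the W118 codon TGG


def junction_read(cdr3: str, read_id="r", tail="", lead=""):
    """Minimal read: [lead][pre motif][+1 nt][cdr3][post motif][tail]."""
    seq = lead + PRE + "T" + cdr3 + POST + tail
    return AmpliconRead(read_id, seq, (40,) * len(seq))


def stopfree(n_nt: int) -> str:
    assert n_nt % 3 == 0
    return "GCT" * (n_nt // 3)


@pytest.fixture(scope="module")
def motifs():
    return default_motif_set("IgM")


class TestLocateJunction:
    def test_constructed_read_located(self, motifs):
        read = junction_read(stopfree(120))
        pre_m, post_m = locate_junction(read, motifs["pre_cdr3"][0], motifs["post_cdr3"][0])
        span = post_m.start - (pre_m.end + 1)
        assert span == 120

    def test_missing_post_motif_is_no_call(self, motifs):
        seq = PRE + "T" + stopfree(60)
        read = AmpliconRead("r", seq, (40,) * len(seq))
        assert locate_junction(read, motifs["pre_cdr3"][0], motifs["post_cdr3"][0]) is None

    def test_nearer_post_hit_preferred_over_constant_region_hit(self, motifs):
        # second post-motif far downstream must not displace the near one
        read = junction_read(stopfree(90), tail=stopfree(60) + POST)
        pre_m, post_m = locate_junction(read, motifs["pre_cdr3"][0], motifs["post_cdr3"][0])
        assert post_m.start - (pre_m.end + 1) == 90

    def test_far_hit_used_only_when_span_stays_under_cap(self, motifs):
        # a single post hit implying >= 225 nt is not an acceptable junction
        read = junction_read(stopfree(240))
        assert locate_junction(read, motifs["pre_cdr3"][0], motifs["post_cdr3"][0]) is None


class TestExciseAndClassify:
    @pytest.mark.parametrize(
        "nt_len,expected",
        [
            (3, Cdr3Class.REJECTED),
            (225, Cdr3Class.REJECTED),
            (240, Cdr3Class.REJECTED),
            (30, Cdr3Class.SHORT),       # 10 aa
            (33, Cdr3Class.MEDIUM),      # 11 aa
            (117, Cdr3Class.MEDIUM),     # 39 aa
            (120, Cdr3Class.ULTRALONG),  # 40 aa
            (222, Cdr3Class.ULTRALONG),  # 74 aa
        ],
    )
    def test_length_classification_boundaries(self, nt_len, expected):
        assert classify_length(nt_len) is expected

    def test_excision_recovers_sequence_and_lengths(self, motifs):
        cdr3 = stopfree(120)
        read = junction_read(cdr3)
        call = call_cdr3(read, motifs)
        assert call.cdr3_nt == cdr3
        assert (call.nt_len, call.aa_len) == (120, 40)
        assert call.cdr3_class is Cdr3Class.ULTRALONG
        assert call.in_frame and call.productive

    def test_short_call(self, motifs):
        call = call_cdr3(junction_read(stopfree(30)), motifs)
        assert (call.aa_len, call.cdr3_class) == (10, Cdr3Class.SHORT)

    def test_three_nt_span_rejected(self, motifs):
        call = call_cdr3(junction_read("GCT"), motifs)
        assert call.cdr3_class is Cdr3Class.REJECTED
        assert not call.productive

    def test_negative_span_collapses_to_rejected(self, motifs):
        read = junction_read(stopfree(30))
        pre_m = MatchResult(0, len(PRE), 0)
        post_m = MatchResult(2, 2 + len(POST), 0)  # upstream of the pre end
        call = excise_cdr3(read, pre_m, post_m, motifs["pre_cdr3"][0], motifs["post_cdr3"][0])
        assert call.cdr3_class is Cdr3Class.REJECTED
        assert call.nt_len == 0


class TestTranslationWindow:
    def test_in_frame_stop_breaks_productivity(self, motifs):
        productive = call_cdr3(junction_read(stopfree(117)), motifs)
        with_stop = call_cdr3(junction_read(stopfree(57) + "TAA" + stopfree(57)), motifs)
        assert productive.productive
        assert not with_stop.productive
        assert with_stop.cdr3_class is Cdr3Class.MEDIUM  # DNA tally unaffected

    def test_frameshifted_span_is_not_productive_but_tallied(self, motifs):
        call = call_cdr3(junction_read(stopfree(120) + "G"), motifs)
        assert call.nt_len == 121
        assert call.aa_len == 40
        assert not call.in_frame
        assert not call.productive

    def test_window_covers_junction_and_is_codon_aligned(self, motifs):
        read = junction_read(stopfree(21))
        pre_m, post_m = locate_junction(read, motifs["pre_cdr3"][0], motifs["post_cdr3"][0])
        window, stop_free = translate_window(
            read, pre_m, post_m, motifs["pre_cdr3"][0], motifs["post_cdr3"][0]
        )
        assert stop_free
        aa = translate(window.window_nt)
        # FWR3 tail ... C104 ... CDR3 (7 aa of Ala) ... W118-G-Q
        assert aa.startswith("EDTATYYC")
        assert aa.endswith("AAAAAAAWGQ")

    def test_n_translates_as_x_and_does_not_block_productivity(self, motifs):
        call = call_cdr3(junction_read(stopfree(57) + "ANT" + stopfree(57)), motifs)
        assert call.productive
        assert translate("ANT") == "X"

    def test_dna_and_protein_denominators_diverge_by_injected_defects(self, motifs):
        """On simulated data the productive shortfall equals the injected
        nonproductive fraction exactly (zero sequencing error)."""
        cfg = SimConfig(
            n_reads=200, seed=5, isotype="IgM", flip_fraction=0.0,
            contaminant_fraction=0.0, nonproductive_fraction=0.3,
            substitution_rate=0.0, insertion_rate=0.0, deletion_rate=0.0,
            short_aa_range=(2, 10),  # avoid the 3-nt removal boundary
        )
        reads, manifest = generate(cfg)
        calls = extract_cdr3s(reads, motifs)
        n_nonproductive_truth = int((~manifest.productive_truth).sum())
        identified = [c for c in calls if c.cdr3_class is not Cdr3Class.REJECTED]
        productive = [c for c in identified if c.productive]
        assert len(identified) == len(reads)
        assert len(identified) - len(productive) == n_nonproductive_truth


class TestPartition:
    def test_every_identified_call_has_exactly_one_class(self, clean_igg_batch, igg_motifs, filter_config):
        _, reads, _ = clean_igg_batch
        merged, _ = rslb_filter(reads, "IgG", igg_motifs, filter_config)
        calls = extract_cdr3s(merged, igg_motifs, filter_config)
        for c in calls:
            assert c.cdr3_class in (
                Cdr3Class.SHORT, Cdr3Class.MEDIUM, Cdr3Class.ULTRALONG, Cdr3Class.REJECTED
            )
            if c.cdr3_class is not Cdr3Class.REJECTED:
                assert 1 <= c.aa_len <= 75
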