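"""CDR3 junction location, excision, translation, and classification.

The CDR3 is measured exclusively between the conserved C104 cysteine at
the end of FWR3 and the W118 tryptophan opening FWR4 (IMGT numbering):
neither anchor residue counts toward the length.  At the DNA level the
amino-acid-equivalent length is ``nt_len // 3`` and spans of ≤ 3 nt or
≥ 225 nt are rejected outright, so valid calls fall in the 1–75 aa
window.  The protein path translates the codon-aligned junction window
(FWR3 position ~99 through FWR4 position 120) and flags a call as
productive only when the span is in frame and the window is free of
stop codons; an ``N`` translates as ``X`` and never blocks productivity
by itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .config import FilterConfig
from .seq_core import (
    AmpliconRead,
    MatchResult,
    MotifSpec,
    find_fuzzy,
    find_fuzzy_all,
    iter_codons,
    translate,
    STOP_CODONS,
)


class Cdr3Class(str, Enum):
    SHORT = "short"
    MEDIUM = "medium"
    ULTRALONG = "ultralong"
    REJECTED = "rejected"


@dataclass(frozen=True)
class JunctionWindow:
    """The codon-aligned nucleotide window spanning FWR3 into FWR4."""

    window_nt: str
    frame_offset: int


@dataclass(frozen=True)
class Cdr3Call:
    """Per-read CDR3 result (DNA-level fields plus the productive flag)."""

    read_id: str
    cdr3_nt: str
    nt_len: int
    aa_len: int
    in_frame: bool
    productive: bool
    cdr3_class: Cdr3Class
    pre_match: MatchResult
    post_match: MatchResult


def classify_length(nt_len: int, config: FilterConfig | None = None) -> Cdr3Class:
    """DNA-level class from the junction span in nt.

    Spans ≤ 3 nt or ≥ 225 nt are rejected; otherwise ``aa = nt // 3``
    yields short (≤ 10 aa), ultralong (≥ 40 aa), or medium.
    """
    cfg = config or _DEFAULT_CFG
    if nt_len < cfg.min_cdr3_nt or nt_len >= cfg.max_cdr3_nt:
        return Cdr3Class.REJECTED
    aa = nt_len // 3
    if aa <= cfg.short_max_aa:
        return Cdr3Class.SHORT
    if aa >= cfg.ultralong_min_aa:
        return Cdr3Class.ULTRALONG
    return Cdr3Class.MEDIUM


_DEFAULT_CFG = FilterConfig()


def _implied_span(pre: MotifSpec, post: MotifSpec,
                  pre_match: MatchResult, post_match: MatchResult) -> int:
    start = pre_match.end + pre.cdr3_boundary_offset
    end = post_match.start + post.cdr3_boundary_offset
    return end - start


def locate_junction(
    read: AmpliconRead,
    pre_motif: MotifSpec,
    post_motif: MotifSpec,
    max_cdr3_nt: int = 225,
) -> tuple[MatchResult, MatchResult] | None:
    """Find the CDR3 flanks: leftmost pre-CDR3 hit, then the nearest
    post-CDR3 hit strictly downstream whose implied span is < 225 nt.

    Returns ``None`` (a no-call, excluded from the CDR3-identified
    denominator) when either flank is absent.  The span cap rejects
    post-motif look-alikes much further downstream in the constant
    region in favour of — or, when no near hit exists, instead of — a
    biologically implausible junction.
    """
    pre_match = find_fuzzy(read.seq, pre_motif)
    if pre_match is None:
        return None
    for post_match in find_fuzzy_all(read.seq, post_motif):
        if post_match.start < pre_match.end:
            continue
        span = _implied_span(pre_motif, post_motif, pre_match, post_match)
        if span < max_cdr3_nt:
            return pre_match, post_match
    return None


def excise_cdr3(
    read: AmpliconRead,
    pre_match: MatchResult,
    post_match: MatchResult,
    pre_motif: MotifSpec,
    post_motif: MotifSpec,
    config: FilterConfig | None = None,
) -> Cdr3Call:
    """Cut the junction out of the read and populate lengths, frame,
    productivity, and the DNA-level class."""
    cfg = config or _DEFAULT_CFG
    start = pre_match.end + pre_motif.cdr3_boundary_offset
    end = post_match.start + post_motif.cdr3_boundary_offset
    nt_len = max(end - start, 0)  # negative span collapses to a rejected call
    cdr3_nt = read.seq[start:end] if end > start else ""
    cdr3_class = classify_length(nt_len, cfg)
    in_frame = nt_len % 3 == 0 and nt_len > 0
    window, productive = translate_window(
        read, pre_match, post_match, pre_motif, post_motif
    )
    if not in_frame:
        productive = False
    return Cdr3Call(
        read_id=read.read_id,
        cdr3_nt=cdr3_nt,
        nt_len=nt_len,
        aa_len=nt_len // 3,
        in_frame=in_frame,
        productive=productive and cdr3_class is not Cdr3Class.REJECTED,
        cdr3_class=cdr3_class,
        pre_match=pre_match,
        post_match=post_match,
    )


def translate_window(
    read: AmpliconRead,
    pre_match: MatchResult,
    post_match: MatchResult,
    pre_motif: MotifSpec,
    post_motif: MotifSpec,
) -> tuple[JunctionWindow, bool]:
    """Translate the codon-aligned FWR3→FWR4 window and report stop-freedom.

    The frame is anchored at ``pre_match.start + pre_motif.frame_offset``;
    the window runs through the end of the post-CDR3 motif (the W118
    codon and the FWR4 residues the motif covers), trimmed to a whole
    number of codons.  Returns the window plus a flag that is True when
    no bona fide stop codon (TAA/TAG/TGA) occurs in the window; ``N``
    codons translate as ``X`` and do not clear the flag.
    """
    w_start = pre_match.start + pre_motif.frame_offset
    w_end = min(post_match.end, len(read.seq))
    nt = read.seq[w_start:w_end]
    stop_free = all(codon not in STOP_CODONS for codon in iter_codons(nt))
    return JunctionWindow(window_nt=nt, frame_offset=pre_motif.frame_offset), stop_free


def call_cdr3(
    read: AmpliconRead,
    motif_set: Mapping[str, list[MotifSpec]],
    config: FilterConfig | None = None,
) -> Cdr3Call | None:
    """Locate + excise for one forward-oriented read; ``None`` on no-call."""
    cfg = config or _DEFAULT_CFG
    (pre_motif,) = motif_set["pre_cdr3"]
    (post_motif,) = motif_set["post_cdr3"]
    located = locate_junction(read, pre_motif, post_motif, cfg.max_cdr3_nt)
    if located is None:
        return None
    pre_match, post_match = located
    return excise_cdr3(read, pre_match, post_match, pre_motif, post_motif, cfg)


def extract_cdr3s(
    reads: Iterable[AmpliconRead],
    motif_set: Mapping[str, list[MotifSpec]],
    config: FilterConfig | None = None,
) -> list[Cdr3Call]:
    """CDR3 calls for every read with a locatable junction (no-calls dropped)."""
    calls = []
    for read in reads:
        call = call_cdr3(read, motif_set, config)
        if call is not None:
            calls.append(call)
    return calls


def translated_junction(read: AmpliconRead,
                        motif_set: Mapping[str, list[MotifSpec]]) -> str | None:
    """Amino-acid translation of the junction window (diagnostic helper)."""
    (pre_motif,) = motif_set["pre_cdr3"]
    (post_motif,) = motif_set["post_cdr3"]
    located = locate_junction(read, pre_motif, post_motif)
    if located is None:
        return None
    window, _ = translate_window(read, *located, pre_motif, post_motif)
    return translate(window.window_nt)
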