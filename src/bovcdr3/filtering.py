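"""The refined stepwise literature-based (RSLB) read-retention procedure.

Reads are first cleaned on quality and an isotype-specific length
window, then pass an ordered sequence of fuzzy motif gates:

1. forward primer, in the orientation given;
2. isotype motif (IgM: either of two motifs, each with its own budget;
   IgG: one motif) — still in the orientation given;
3. reverse-orientation rescue: the *original cleaned* set is searched
   for the literal reverse primer, and hits are returned in forward
   orientation (a forward read carries the reverse complement of the
   reverse primer, so error-free forward reads are not re-selected);
4. merge of the step-2 and step-3 outputs, deduplicated by read id with
   the step-2 (as-given) copy winning.

The result is a single forward-oriented read set, plus stage counts for
the retention bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .config import FilterConfig
from .seq_core import AmpliconRead, MotifSpec, find_fuzzy


@dataclass
class StageCounts:
    """Read counts surviving each retention stage of one sample."""

    raw: int = 0
    cleaned: int = 0
    step1_forward_primer: int = 0
    step2_isotype_motif: int = 0
    step3_reoriented: int = 0
    merged_unique: int = 0
    cdr3_identified: int = 0
    productive: int = 0

    def validate(self) -> None:
        """Assert the monotonicity every run must satisfy."""
        assert self.cleaned <= self.raw
        assert self.step1_forward_primer <= self.cleaned
        assert self.step2_isotype_motif <= self.step1_forward_primer
        assert self.step3_reoriented <= self.cleaned
        assert self.merged_unique <= self.step2_isotype_motif + self.step3_reoriented
        assert self.cdr3_identified <= self.merged_unique
        assert self.productive <= self.cdr3_identified

    def as_rows(self, sample: str) -> list[tuple[str, str, int]]:
        return [
            (sample, stage, getattr(self, stage))
            for stage in (
                "raw", "cleaned", "step1_forward_primer", "step2_isotype_motif",
                "step3_reoriented", "merged_unique", "cdr3_identified", "productive",
            )
        ]


def passes_quality(read: AmpliconRead, config: FilterConfig) -> bool:
    """True when at most the allowed fraction of bases sit below the Phred gate."""
    below = sum(1 for q in read.quals if q < config.min_qual)
    return below / len(read.quals) <= config.max_unqualified_fraction


def clean_reads(
    reads: Iterable[AmpliconRead], isotype: str, config: FilterConfig
) -> tuple[list[AmpliconRead], StageCounts]:
    """Quality and length gate.

    A read is retained iff the fraction of bases below ``min_qual`` is at
    most ``max_unqualified_fraction`` *and* its length lies inside the
    isotype's inclusive window.
    """
    lo, hi = config.length_window(isotype)
    counts = StageCounts()
    kept: list[AmpliconRead] = []
    for read in reads:
        counts.raw += 1
        if lo <= len(read) <= hi and passes_quality(read, config):
            kept.append(read)
    counts.cleaned = len(kept)
    return kept, counts


def step1_forward_primer(
    reads: Sequence[AmpliconRead], motif_set: Mapping[str, list[MotifSpec]]
) -> list[AmpliconRead]:
    """Reads containing the forward primer within budget, as given."""
    (primer,) = motif_set["forward_primer"]
    return [r for r in reads if find_fuzzy(r.seq, primer) is not None]


def step2_isotype_motif(
    step1_reads: Sequence[AmpliconRead], motif_set: Mapping[str, list[MotifSpec]]
) -> list[AmpliconRead]:
    """Reads matching any configured isotype motif within its own budget."""
    motifs = motif_set["isotype_motif"]
    return [
        r for r in step1_reads
        if any(find_fuzzy(r.seq, m) is not None for m in motifs)
    ]


def step3_reverse_rescue(
    cleaned_reads: Sequence[AmpliconRead],
    motif_set: Mapping[str, list[MotifSpec]],
    config: FilterConfig | None = None,
) -> list[AmpliconRead]:
    """Rescue reverse-oriented reads from the full cleaned set.

    Reads containing the *literal* reverse primer within budget are
    reverse-complemented and emitted in forward orientation.  With
    ``recheck_isotype_after_reorient`` set, the re-oriented read must
    additionally carry an isotype motif.
    """
    (rev,) = motif_set["reverse_primer"]
    rescued = [
        r.reverse_complemented()
        for r in cleaned_reads
        if find_fuzzy(r.seq, rev) is not None
    ]
    if config is not None and config.recheck_isotype_after_reorient:
        motifs = motif_set["isotype_motif"]
        rescued = [
            r for r in rescued
            if any(find_fuzzy(r.seq, m) is not None for m in motifs)
        ]
    return rescued


def merge_dedupe(
    step2_reads: Sequence[AmpliconRead], step3_reads: Sequence[AmpliconRead]
) -> list[AmpliconRead]:
    """Union keyed by read id; the step-2 (as-given) copy wins on collision."""
    merged: dict[str, AmpliconRead] = {}
    for read in step2_reads:
        merged.setdefault(read.read_id, read)
    for read in step3_reads:
        merged.setdefault(read.read_id, read)
    return list(merged.values())


def rslb_filter(
    reads: Iterable[AmpliconRead],
    isotype: str,
    motif_set: Mapping[str, list[MotifSpec]],
    config: FilterConfig,
) -> tuple[list[AmpliconRead], StageCounts]:
    """Run cleaning plus the four stepwise gates; return the merged
    forward-oriented set and the per-stage counts."""
    cleaned, counts = clean_reads(reads, isotype, config)
    s1 = step1_forward_primer(cleaned, motif_set)
    s2 = step2_isotype_motif(s1, motif_set)
    s3 = step3_reverse_rescue(cleaned, motif_set, config)
    merged = merge_dedupe(s2, s3)
    counts = replace(
        counts,
        step1_forward_primer=len(s1),
        step2_isotype_motif=len(s2),
        step3_reoriented=len(s3),
        merged_unique=len(merged),
    )
    counts.validate()
    return merged, counts
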