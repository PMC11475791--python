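"""End-to-end orchestration: clean → stepwise filter → CDR3 extraction → summary.

``run_pipeline`` processes every sample of a sample sheet (cow, tissue,
isotype, FASTQ path) with one configuration and writes three TSVs into
the output directory: per-stage retention counts, per-read CDR3 calls,
and per-sample summary percentages.  A sample that fails (for example,
nothing survives cleaning) is flagged in the summary and the run
continues; the return value carries the per-sample outcomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import RunConfig, load_config
from .extraction import extract_cdr3s
from .fastq_io import read_fastq, write_fastq, write_tsv
from .filtering import rslb_filter
from .stats import RepertoireSummary, summarize

logger = logging.getLogger("bovcdr3")


@dataclass(frozen=True)
class SampleSheetRow:
    cow_id: str
    tissue: str
    isotype: str
    fastq_path: str

    @property
    def sample(self) -> str:
        return f"{self.cow_id}_{self.tissue}_{self.isotype}"


@dataclass
class PipelineResult:
    summaries: list[RepertoireSummary] = field(default_factory=list)
    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def load_sample_sheet(path: str | Path) -> list[SampleSheetRow]:
    """Read a sample sheet TSV with columns cow, tissue, isotype, fastq."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"cow", "tissue", "isotype", "fastq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path}: missing columns {sorted(missing)}")
    rows = [
        SampleSheetRow(r.cow, r.tissue, r.isotype, r.fastq)
        for r in df.itertuples()
    ]
    keys = [r.sample for r in rows]
    if len(set(keys)) != len(keys):
        raise ValueError(f"sample sheet {path}: duplicate sample keys")
    return rows


def process_sample(
    row: SampleSheetRow, config: RunConfig
) -> tuple[RepertoireSummary, pd.DataFrame, list]:
    """Run the whole method on one sample; returns the summary, the
    per-read CDR3 table, and the retained forward-oriented reads."""
    reads = read_fastq(row.fastq_path, row.cow_id, row.tissue, row.isotype)
    motif_set = config.motif_set(row.isotype)
    retained, counts = rslb_filter(reads, row.isotype, motif_set, config.filter)
    logger.info(
        "%s: raw=%d cleaned=%d step1=%d step2=%d step3=%d merged=%d",
        row.sample, counts.raw, counts.cleaned, counts.step1_forward_primer,
        counts.step2_isotype_motif, counts.step3_reoriented, counts.merged_unique,
    )
    calls = extract_cdr3s(retained, motif_set, config.filter)
    summary = summarize(row.sample, calls, counts)
    logger.info(
        "%s: cdr3_identified=%d productive=%d",
        row.sample, counts.cdr3_identified, counts.productive,
    )
    call_table = pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "cdr3_nt": c.cdr3_nt,
                "nt_len": c.nt_len,
                "aa_len": c.aa_len,
                "in_frame": c.in_frame,
                "productive": c.productive,
                "class": c.cdr3_class.value,
                "sample": row.sample,
            }
            for c in calls
        ],
        columns=["read_id", "cdr3_nt", "nt_len", "aa_len",
                 "in_frame", "productive", "class", "sample"],
    )
    return summary, call_table, retained


def run_pipeline(
    sample_rows: Sequence[SampleSheetRow],
    out_dir: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
    write_retained_fastq: bool = False,
) -> PipelineResult:
    """Process every sample and write stage-count, CDR3, and summary TSVs."""
    config = config or load_config()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()
    count_rows, call_tables, summary_rows = [], [], []
    for row in sample_rows:
        try:
            summary, call_table, retained = process_sample(row, config)
        except Exception as exc:  # per-sample failure, run continues
            logger.error("%s: failed: %s", row.sample, exc)
            result.failures.append((row.sample, str(exc)))
            summary_rows.append({"sample": row.sample, "error": str(exc)})
            continue
        result.summaries.append(summary)
        count_rows.extend(
            {"sample": s, "stage": stage, "count": n}
            for s, stage, n in summary.counts.as_rows(row.sample)
        )
        call_tables.append(call_table)
        summary_rows.append({
            "sample": row.sample,
            "cdr3_identified": summary.pct_ultralong_dna.denominator,
            "productive": summary.pct_ultralong_protein.denominator,
            "pct_ultralong_dna": summary.pct_ultralong_dna.rounded,
            "pct_ultralong_protein": summary.pct_ultralong_protein.rounded,
            "pct_short_protein": summary.pct_short_protein.rounded,
            "flags": "; ".join(summary.flags),
        })
        if write_retained_fastq:
            write_fastq(retained, out_dir / f"{row.sample}.retained.fastq")
    digest = config.digest
    write_tsv(pd.DataFrame(count_rows), out_dir / "stage_counts.tsv", digest, seed)
    calls_df = (
        pd.concat(call_tables, ignore_index=True) if call_tables else pd.DataFrame()
    )
    write_tsv(calls_df, out_dir / "cdr3_calls.tsv", digest, seed)
    write_tsv(pd.DataFrame(summary_rows), out_dir / "summary.tsv", digest, seed)
    return result
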