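"""FASTQ and TSV input/output.

FASTQ handling assumes the modern 4-line record convention with
Phred+33 qualities (multi-line records are rejected); ``.gz`` paths are
transparently (de)compressed.  Parsing is delegated to Biopython's
fast FASTQ iterator, with errors re-raised naming the record number.

Every TSV written by the pipeline starts with a provenance comment
(tool version, config digest, seed) followed by a header row.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import __version__
from .seq_core import AmpliconRead


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(
    path: str | Path,
    cow_id: str = "",
    tissue: str = "",
    isotype: str = "",
) -> Iterator[AmpliconRead]:
    """Stream reads from a (optionally gzipped) 4-line FASTQ file.

    Raises
    ------
    ValueError
        On a malformed or truncated record, naming the record number,
        or on a sequence/quality length mismatch.
    """
    record_no = 0
    with _open_text(path) as fh:
        iterator = FastqGeneralIterator(fh)
        while True:
            record_no += 1
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed FASTQ at record {record_no}: {exc}"
                ) from exc
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: record {record_no}: sequence length {len(seq)} "
                    f"!= quality length {len(qual)}"
                )
            read_id = title.split(None, 1)[0]
            yield AmpliconRead(
                read_id=read_id,
                seq=seq.upper(),
                quals=tuple(ord(c) - 33 for c in qual),
                cow_id=cow_id,
                tissue=tissue,
                isotype=isotype,
            )


def write_fastq(reads: Iterable[AmpliconRead], path: str | Path) -> int:
    """Write reads as 4-line Phred+33 FASTQ; returns the record count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            fh.write(f"@{read.read_id}\n{read.seq}\n+\n{qual}\n")
            n += 1
    return n


def provenance_comment(config_digest: str = "", seed: int | None = None) -> str:
    parts = [f"bovcdr3 v{__version__}"]
    if config_digest:
        parts.append(f"config={config_digest}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return "# " + " ".join(parts)


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    config_digest: str = "",
    seed: int | None = None,
) -> None:
    """Write a TSV with a leading provenance comment and a header row."""
    with open(path, "w") as fh:
        fh.write(provenance_comment(config_digest, seed) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` (comment lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")
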