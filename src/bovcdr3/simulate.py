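"""Synthetic bovine IgH amplicon generator with a ground-truth manifest.

Templates follow the amplicon architecture the pipeline assumes::

    [forward primer][FWR1-3 scaffold][pre-CDR3 motif][+1 nt][CDR3]
    [post-CDR3 motif][FWR4/constant filler][isotype motif][revcomp(reverse primer)]

The CDR3 is built from random stop-free codons of a requested
amino-acid length (one in-frame stop is injected for non-productive
reads), so the constructed truth is recoverable exactly by the
extraction stage on error-free data.  The scaffold and filler are fixed
pseudo-germline stretches, stop-free in the anchored frame.  To keep
the manifest a valid oracle, a candidate template is rejected and its
CDR3 re-drawn whenever the shipped default motifs would (a) locate a
junction different from the constructed one, or (b) spuriously capture
the reverse-complemented template in the wrong orientation.

Reads are drawn from a three-component class mixture (short / medium /
ultralong), a configurable fraction are emitted reverse-complemented,
a contaminant fraction carries no primers at all, and an independent
per-base substitution/insertion/deletion error model with Gaussian
Phred qualities can be layered on top.  The manifest records the truth
*before* error application.  Same seed and config give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import (
    FORWARD_PRIMER,
    IGG_ISOTYPE_MOTIF,
    IGG_REVERSE_PRIMER,
    IGM_ISOTYPE_MOTIF_LONG,
    IGM_REVERSE_PRIMER,
    POST_CDR3_EXEMPLAR,
    PRE_CDR3_EXEMPLAR,
    default_motif_set,
)
from .seq_core import AmpliconRead, MotifSpec, find_fuzzy, reverse_complement

_BASES = np.array(list("ACGT"))
_STOPFREE_CODONS = np.array(sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
))
_STOP_CODON_CHOICES = np.array(["TAA", "TAG", "TGA"])

# C104 codon completion: the pre-CDR3 exemplar ends two bases (TG) into
# the conserved cysteine codon; this base completes TGT.
_C104_THIRD_BASE = "T"


def _fixed_stopfree_stretch(n_codons: int, seed: int) -> str:
    """A fixed pseudo-germline stretch of stop-free codons."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(_STOPFREE_CODONS, size=n_codons))


# Fixed scaffolds, generated once; long enough for the largest IgM template.
FWR_SCAFFOLD = _fixed_stopfree_stretch(300, seed=704401)       # up to 900 nt FWR1-3
FWR4_FILLER = _fixed_stopfree_stretch(20, seed=704402)         # 60 nt constant-side


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults define the simulated study conditions."""

    n_reads: int
    seed: int
    isotype: str = "IgM"
    class_mix: tuple[float, float, float] = (0.05, 0.87, 0.08)  # short/medium/ultralong
    short_aa_range: tuple[int, int] = (1, 10)
    medium_aa_range: tuple[int, int] = (11, 39)
    ultralong_aa_range: tuple[int, int] = (40, 70)
    flip_fraction: float = 0.5
    nonproductive_fraction: float = 0.2
    contaminant_fraction: float = 0.05
    substitution_rate: float = 0.005
    insertion_rate: float = 0.0025
    deletion_rate: float = 0.0025
    quality_mean: float = 20.0
    quality_sd: float = 6.0
    target_length: int | None = None  # default: mid-window for the isotype

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix probabilities must sum to 1")
        for rate in (self.flip_fraction, self.nonproductive_fraction,
                     self.contaminant_fraction, self.substitution_rate,
                     self.insertion_rate, self.deletion_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates and fractions must lie in [0, 1]")
        if self.isotype not in ("IgM", "IgG"):
            raise ValueError(f"unknown isotype {self.isotype!r}")

    @property
    def resolved_target_length(self) -> int:
        if self.target_length is not None:
            return self.target_length
        return {"IgM": 900, "IgG": 450}[self.isotype]


_ISOTYPE_PARTS = {
    "IgM": (IGM_ISOTYPE_MOTIF_LONG, IGM_REVERSE_PRIMER),
    "IgG": (IGG_ISOTYPE_MOTIF, IGG_REVERSE_PRIMER),
}


def _random_cdr3(rng: np.random.Generator, aa_len: int, productive: bool) -> str:
    codons = list(rng.choice(_STOPFREE_CODONS, size=aa_len))
    if not productive:
        codons[int(rng.integers(aa_len))] = str(rng.choice(_STOP_CODON_CHOICES))
    return "".join(codons)


def _template_recovers_truth(
    seq: str, aa_len: int, motif_set: Mapping[str, list[MotifSpec]]
) -> bool:
    """Check the template is unambiguous for the pipeline.

    Forward orientation must yield the constructed junction exactly;
    the reverse complement must not be capturable in the wrong
    orientation (forward primer *and* isotype motif both matching).
    """
    from .extraction import locate_junction  # local import to avoid a cycle

    (pre,) = motif_set["pre_cdr3"]
    (post,) = motif_set["post_cdr3"]
    read = AmpliconRead("check", seq, (40,) * len(seq))
    located = locate_junction(read, pre, post)
    if located is None:
        return False
    pre_match, post_match = located
    span = (post_match.start + post.cdr3_boundary_offset) - (
        pre_match.end + pre.cdr3_boundary_offset
    )
    if span != 3 * aa_len:
        return False
    rc = reverse_complement(seq)
    (fwd,) = motif_set["forward_primer"]
    if find_fuzzy(rc, fwd) is not None and any(
        find_fuzzy(rc, m) is not None for m in motif_set["isotype_motif"]
    ):
        return False
    return True


def build_template(
    isotype: str,
    aa_len: int,
    productive: bool,
    rng: np.random.Generator,
    target_length: int | None = None,
    max_attempts: int = 100,
) -> str:
    """Assemble one forward-oriented amplicon template.

    The FWR scaffold length is auto-adjusted so the total sits at the
    isotype's target length (inside the cleaning window).  The random
    CDR3 is re-drawn until the template is unambiguous for the default
    motif set.
    """
    if not 1 <= aa_len <= 75:
        raise ValueError(f"aa_len must be in [1, 75], got {aa_len}")
    iso_motif, rev_primer = _ISOTYPE_PARTS[isotype]
    total = target_length or {"IgM": 900, "IgG": 450}[isotype]
    fixed_len = (
        len(FORWARD_PRIMER) + len(PRE_CDR3_EXEMPLAR) + 1 + len(POST_CDR3_EXEMPLAR)
        + len(FWR4_FILLER) + len(iso_motif) + len(rev_primer)
    )
    scaffold_len = total - fixed_len - 3 * aa_len
    if scaffold_len < 0:
        raise ValueError(
            f"target length {total} too small for aa_len {aa_len} ({isotype})"
        )
    if scaffold_len > len(FWR_SCAFFOLD):
        raise ValueError("target length exceeds the shipped scaffold capacity")
    scaffold = FWR_SCAFFOLD[:scaffold_len]
    motif_set = default_motif_set(isotype)
    for _ in range(max_attempts):
        cdr3 = _random_cdr3(rng, aa_len, productive)
        seq = (
            FORWARD_PRIMER + scaffold + PRE_CDR3_EXEMPLAR + _C104_THIRD_BASE
            + cdr3 + POST_CDR3_EXEMPLAR + FWR4_FILLER + iso_motif
            + reverse_complement(rev_primer)
        )
        if _template_recovers_truth(seq, aa_len, motif_set):
            return seq
    raise RuntimeError(
        f"could not build an unambiguous template (isotype={isotype}, aa_len={aa_len})"
    )


def _apply_errors(
    seq: str, config: SimConfig, rng: np.random.Generator
) -> tuple[str, int]:
    """Independent per-base substitution/insertion/deletion errors."""
    if config.substitution_rate == config.insertion_rate == config.deletion_rate == 0.0:
        return seq, 0
    out: list[str] = []
    n_errors = 0
    for base in seq:
        r = rng.random()
        if r < config.deletion_rate:
            n_errors += 1
            continue
        if r < config.deletion_rate + config.substitution_rate:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[int(rng.integers(3))])
            n_errors += 1
        else:
            out.append(base)
        if rng.random() < config.insertion_rate:
            out.append(str(rng.choice(_BASES)))
            n_errors += 1
    if not out:  # pathological rates; keep the read non-empty
        out.append(seq[0])
    return "".join(out), n_errors


def _qualities(n: int, config: SimConfig, rng: np.random.Generator) -> tuple[int, ...]:
    q = rng.normal(config.quality_mean, config.quality_sd, size=n)
    return tuple(int(v) for v in np.clip(np.rint(q), 2, 41))


_CLASS_NAMES = ("short", "medium", "ultralong")


def generate(config: SimConfig) -> tuple[list[AmpliconRead], pd.DataFrame]:
    """Draw ``n_reads`` synthetic amplicons plus their truth manifest.

    Manifest columns: ``read_id, true_class, true_aa_len,
    true_orientation, productive_truth, injected_error_count``.
    Contaminant reads (no primers, random sequence in the length
    window) carry ``true_class="contaminant"`` and ``true_aa_len=-1``.

    Template construction, error injection, and quality drawing use
    independent RNG streams derived from the seed, so two runs that
    differ only in their error rates share identical underlying
    templates.
    """
    rng = np.random.default_rng([config.seed, 0])
    rng_err = np.random.default_rng([config.seed, 1])
    rng_qual = np.random.default_rng([config.seed, 2])
    aa_ranges = {
        "short": config.short_aa_range,
        "medium": config.medium_aa_range,
        "ultralong": config.ultralong_aa_range,
    }
    reads: list[AmpliconRead] = []
    manifest_rows: list[dict] = []
    width = len(str(max(config.n_reads, 1)))
    for i in range(config.n_reads):
        read_id = f"sim{i:0{width}d}"
        is_contaminant = rng.random() < config.contaminant_fraction
        flip = rng.random() < config.flip_fraction
        if is_contaminant:
            seq = "".join(rng.choice(_BASES, size=config.resolved_target_length))
            true_class, aa_len, productive = "contaminant", -1, False
        else:
            true_class = _CLASS_NAMES[
                int(rng.choice(3, p=np.asarray(config.class_mix)))
            ]
            lo, hi = aa_ranges[true_class]
            aa_len = int(rng.integers(lo, hi + 1))
            productive = rng.random() >= config.nonproductive_fraction
            seq = build_template(
                config.isotype, aa_len, productive, rng,
                target_length=config.target_length,
            )
        if flip:
            seq = reverse_complement(seq)
        seq, n_errors = _apply_errors(seq, config, rng_err)
        quals = _qualities(len(seq), config, rng_qual)
        reads.append(AmpliconRead(
            read_id=read_id, seq=seq, quals=quals, isotype=config.isotype,
        ))
        manifest_rows.append({
            "read_id": read_id,
            "true_class": true_class,
            "true_aa_len": aa_len,
            "true_orientation": "reverse-complemented" if flip else "as-given",
            "productive_truth": bool(productive),
            "injected_error_count": n_errors,
        })
    manifest = pd.DataFrame(manifest_rows)
    return reads, manifest
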