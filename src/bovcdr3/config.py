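"""Motif sets, filtering thresholds, and the run configuration file.

The shipped defaults encode the published bovine IgH amplicon design:
a single forward primer in FWR1 shared by both isotypes, an
isotype-specific constant-region motif (two alternatives for IgM, one
for IgG), an isotype-specific reverse primer used to rescue
reverse-oriented reads, and the conserved FWR3/FWR4 motifs flanking the
CDR3.  Every threshold is a config key; ``dump_default_config`` writes
the whole thing as editable YAML and ``load_config`` reads it back.

CDR3 boundary arithmetic: the pre-CDR3 exemplar ``GAGGACACGGCCACATACTACTG``
ends two bases into the conserved C104 codon (TG of TGT/TGC), so one
further base completes that codon before the CDR3 starts
(``cdr3_boundary_offset = +1``); its start is codon-aligned
(``frame_offset = 0``).  The post-CDR3 motif opens with the W118 codon
TGG, so the CDR3 ends exactly at the match start (offset 0).  With the
junction measured exclusively between C104 and W118, the 1–75 aa window
corresponds to spans of 4–224 nt.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .seq_core import MotifRole, MotifSpec

ISOTYPES = ("IgM", "IgG")

FORWARD_PRIMER = "AGATGAACCCACTGTGGACC"
IGM_ISOTYPE_MOTIF_LONG = "AATCACACCCGAGAGTCTTC"
IGM_ISOTYPE_MOTIF_SHORT = "ACAGCCTCTCT"
IGM_REVERSE_PRIMER = "TGTTTGGGGCTGAAGTCC"
IGG_ISOTYPE_MOTIF = "CTCAGCCTCCACCACAGC"
IGG_REVERSE_PRIMER = "GCTGTGGTGGAGGCTGAG"
PRE_CDR3_EXEMPLAR = "GAGGACACGGCCACATACTACTG"
POST_CDR3_EXEMPLAR = "TGGGGCCAA"

# Editable motif families for the conserved CDR3 flanks.  The pre-CDR3
# family tolerates the common third-position wobble in the FWR3 tail and
# TGT/TGC at C104 via its substitution budget; the post-CDR3 family
# covers the frequent TGGGG(C|T)CAA variation at the FWR4 start.
PRE_CDR3_PATTERN = PRE_CDR3_EXEMPLAR
POST_CDR3_PATTERN = "TGGGG(C|T)CAA"


def default_motif_set(isotype: str) -> dict[str, list[MotifSpec]]:
    """The five-motif RSLB set for one isotype, keyed by stage role."""
    if isotype == "IgM":
        isotype_motifs = [
            MotifSpec("IgM-motif-long", IGM_ISOTYPE_MOTIF_LONG,
                      MotifRole.ISOTYPE_MOTIF, max_subs=4),
            MotifSpec("IgM-motif-short", IGM_ISOTYPE_MOTIF_SHORT,
                      MotifRole.ISOTYPE_MOTIF, max_subs=2),
        ]
        reverse = MotifSpec("IgM-reverse-primer", IGM_REVERSE_PRIMER,
                            MotifRole.REVERSE_PRIMER, max_subs=4)
    elif isotype == "IgG":
        isotype_motifs = [
            MotifSpec("IgG-motif", IGG_ISOTYPE_MOTIF,
                      MotifRole.ISOTYPE_MOTIF, max_subs=3),
        ]
        reverse = MotifSpec("IgG-reverse-primer", IGG_REVERSE_PRIMER,
                            MotifRole.REVERSE_PRIMER, max_subs=3)
    else:
        raise ValueError(f"unknown isotype {isotype!r} (expected IgM or IgG)")
    return {
        "forward_primer": [
            MotifSpec("forward-primer", FORWARD_PRIMER,
                      MotifRole.FORWARD_PRIMER, max_subs=4)
        ],
        "isotype_motif": isotype_motifs,
        "reverse_primer": [reverse],
        "pre_cdr3": [
            MotifSpec("pre-CDR3", PRE_CDR3_PATTERN, MotifRole.PRE_CDR3,
                      max_subs=2, cdr3_boundary_offset=1, frame_offset=0)
        ],
        "post_cdr3": [
            MotifSpec("post-CDR3", POST_CDR3_PATTERN, MotifRole.POST_CDR3,
                      max_subs=1, cdr3_boundary_offset=0)
        ],
    }


# Inclusive per-isotype read-length windows (nt) for the cleaning gate.
LENGTH_WINDOWS: dict[str, tuple[int, int]] = {
    "IgM": (700, 1200),
    "IgG": (200, 800),
}


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for cleaning and the stepwise motif filter.

    ``min_qual``/``max_unqualified_fraction`` implement the per-base
    qualified-quality gate (a read is dropped when more than the given
    fraction of its bases fall below the Phred threshold), matching the
    documented defaults of the standard short/long-read cleaner.
    """

    min_qual: int = 15
    max_unqualified_fraction: float = 0.40
    length_windows: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(LENGTH_WINDOWS)
    )
    recheck_isotype_after_reorient: bool = False
    max_cdr3_nt: int = 225   # spans >= this are not a CDR3 (exclusive cap)
    min_cdr3_nt: int = 4     # spans <= 3 nt are removed
    short_max_aa: int = 10
    ultralong_min_aa: int = 40

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_unqualified_fraction <= 1.0:
            raise ValueError("max_unqualified_fraction must lie in [0, 1]")
        for iso, (lo, hi) in self.length_windows.items():
            if lo >= hi:
                raise ValueError(f"length window for {iso}: min must be < max")

    def length_window(self, isotype: str) -> tuple[int, int]:
        try:
            return self.length_windows[isotype]
        except KeyError:
            raise ValueError(
                f"unknown isotype {isotype!r}; configured: {sorted(self.length_windows)}"
            ) from None


def _motif_to_dict(m: MotifSpec) -> dict:
    return {
        "name": m.name,
        "pattern": m.pattern,
        "role": m.role.value,
        "max_subs": m.max_subs,
        "cdr3_boundary_offset": m.cdr3_boundary_offset,
        "frame_offset": m.frame_offset,
    }


def _motif_from_dict(d: Mapping) -> MotifSpec:
    return MotifSpec(
        name=d["name"],
        pattern=d["pattern"],
        role=MotifRole(d["role"]),
        max_subs=int(d.get("max_subs", 0)),
        cdr3_boundary_offset=int(d.get("cdr3_boundary_offset", 0)),
        frame_offset=int(d.get("frame_offset", 0)),
    )


def default_config_dict() -> dict:
    """The full default configuration as a plain, YAML-serialisable dict."""
    fc = FilterConfig()
    return {
        "filter": {
            "min_qual": fc.min_qual,
            "max_unqualified_fraction": fc.max_unqualified_fraction,
            "length_windows": {iso: list(win) for iso, win in fc.length_windows.items()},
            "recheck_isotype_after_reorient": fc.recheck_isotype_after_reorient,
            "max_cdr3_nt": fc.max_cdr3_nt,
            "min_cdr3_nt": fc.min_cdr3_nt,
            "short_max_aa": fc.short_max_aa,
            "ultralong_min_aa": fc.ultralong_min_aa,
        },
        "motifs": {
            iso: {
                stage: [_motif_to_dict(m) for m in motifs]
                for stage, motifs in default_motif_set(iso).items()
            }
            for iso in ISOTYPES
        },
    }


def dump_default_config() -> str:
    """Render the default configuration as human-editable YAML."""
    return yaml.safe_dump(default_config_dict(), sort_keys=False)


@dataclass(frozen=True)
class RunConfig:
    """A parsed configuration: thresholds plus per-isotype motif sets."""

    filter: FilterConfig
    motifs: Mapping[str, Mapping[str, list[MotifSpec]]]
    digest: str = ""

    def motif_set(self, isotype: str) -> Mapping[str, list[MotifSpec]]:
        try:
            return self.motifs[isotype]
        except KeyError:
            raise ValueError(f"no motif set configured for isotype {isotype!r}") from None


def load_config(path: str | None = None) -> RunConfig:
    """Load a YAML config; with ``path=None`` return the shipped defaults."""
    if path is None:
        raw = default_config_dict()
        text = yaml.safe_dump(raw, sort_keys=True)
    else:
        with open(path) as fh:
            text = fh.read()
        raw = yaml.safe_load(text)
    f = raw.get("filter", {})
    fc = FilterConfig(
        min_qual=int(f.get("min_qual", 15)),
        max_unqualified_fraction=float(f.get("max_unqualified_fraction", 0.40)),
        length_windows={
            iso: (int(w[0]), int(w[1]))
            for iso, w in f.get(
                "length_windows", {k: list(v) for k, v in LENGTH_WINDOWS.items()}
            ).items()
        },
        recheck_isotype_after_reorient=bool(f.get("recheck_isotype_after_reorient", False)),
        max_cdr3_nt=int(f.get("max_cdr3_nt", 225)),
        min_cdr3_nt=int(f.get("min_cdr3_nt", 4)),
        short_max_aa=int(f.get("short_max_aa", 10)),
        ultralong_min_aa=int(f.get("ultralong_min_aa", 40)),
    )
    motifs = {
        iso: {stage: [_motif_from_dict(m) for m in entries]
              for stage, entries in stages.items()}
        for iso, stages in raw["motifs"].items()
    }
    digest = hashlib.sha256(text.encode()).hexdigest()[:12]
    return RunConfig(filter=fc, motifs=motifs, digest=digest)
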