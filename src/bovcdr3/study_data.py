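"""Published per-cow summary percentages used as inputs to the paired statistics.

These are the per-animal ultralong- and short-CDR3 percentages from a
paired blood/colostrum study of seven Holstein-Friesian cows at
calving, in which IgM and IgG heavy-chain amplicons were long-read
sequenced and CDR3s were identified with the stepwise motif-filtering
procedure implemented by this package.  They serve as the worked
example for the statistics layer: reproducing the study's reported
means ± SEM, its paired exact Wilcoxon tests, and its blood↔colostrum
correlations requires only these printed per-cow values, not the raw
sequence data.

Cows are indexed 1–7 in the same order in every tuple.
"""

from __future__ import annotations

from .stats import PairedDesign

COW_IDS = tuple(f"cow{i}" for i in range(1, 8))

# Percentage of productive protein sequences with an ultralong (>= 40 aa) CDR3.
PRODUCTIVE_ULTRALONG = {
    ("blood", "IgM"): (2.23, 4.03, 5.39, 6.70, 5.12, 4.70, 1.38),
    ("colostrum", "IgM"): (0.62, 10.11, 12.24, 7.01, 12.64, 10.51, 3.48),
    ("blood", "IgG"): (3.88, 10.86, 3.04, 4.66, 7.49, 6.75, 9.59),
    ("colostrum", "IgG"): (18.03, 6.67, 10.96, 6.96, 11.89, 19.54, 16.79),
}

# Percentage of DNA-level identified CDR3s that are ultralong.
DNA_ULTRALONG = {
    ("blood", "IgM"): (3.56, 5.86, 8.20, 10.84, 7.69, 6.96, 2.14),
    ("colostrum", "IgM"): (1.23, 14.36, 17.54, 10.87, 17.38, 17.51, 5.10),
    ("blood", "IgG"): (5.85, 14.97, 4.75, 7.58, 11.28, 9.88, 13.76),
    ("colostrum", "IgG"): (19.85, 9.44, 16.79, 11.03, 17.25, 26.17, 27.26),
}

# Percentage of productive protein sequences with a short (<= 10 aa) CDR3.
PRODUCTIVE_SHORT = {
    ("blood", "IgM"): (2.98, 2.48, 2.16, 3.44, 5.67, 4.13, 3.47),
    ("colostrum", "IgM"): (1.75, 2.54, 8.31, 3.69, 8.47, 6.00, 13.77),
    ("blood", "IgG"): (7.13, 4.46, 2.22, 9.48, 11.25, 6.22, 6.16),
    ("colostrum", "IgG"): (1.80, 5.01, 11.47, 8.74, 13.36, 9.11, 1.88),
}


def paired_design(metric: str, isotype: str) -> PairedDesign:
    """Blood-vs-colostrum paired design for one metric and isotype.

    ``metric`` is one of ``productive_ultralong``, ``dna_ultralong``,
    ``productive_short``.
    """
    tables = {
        "productive_ultralong": PRODUCTIVE_ULTRALONG,
        "dna_ultralong": DNA_ULTRALONG,
        "productive_short": PRODUCTIVE_SHORT,
    }
    try:
        table = tables[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(tables)}") from None
    return PairedDesign(
        cow_ids=COW_IDS,
        blood=table[("blood", isotype)],
        colostrum=table[("colostrum", isotype)],
    )
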