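"""Per-sample repertoire summaries and paired nonparametric statistics.

The summary layer reports, with explicit denominators, the three
headline percentages of a repertoire sample: ultralong CDR3s among all
DNA-level identified CDR3s, and ultralong / short CDR3s among
productive protein sequences.  The statistics layer implements the
small-n paired comparisons used to contrast blood and colostrum from
the same cows: mean ± SEM, an *exact* two-sided Wilcoxon signed-rank
test by full enumeration of sign assignments, and product-moment
correlation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .extraction import Cdr3Call, Cdr3Class
from .filtering import StageCounts


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal-style rounding: .005 always goes up (reporting layer only)."""
    factor = 10.0 ** ndigits
    return math.floor(x * factor + 0.5) / factor


@dataclass(frozen=True)
class Percentage:
    """A percentage with its numerator and denominator kept alongside."""

    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def value(self) -> float | None:
        if not self.defined:
            return None
        return 100.0 * self.numerator / self.denominator

    @property
    def rounded(self) -> float | None:
        return None if self.value is None else round_half_up(self.value)


@dataclass
class RepertoireSummary:
    """Stage counts and headline percentages for one sample."""

    sample: str
    counts: StageCounts
    pct_ultralong_dna: Percentage
    pct_ultralong_protein: Percentage
    pct_short_protein: Percentage
    flags: list[str] = field(default_factory=list)


def summarize(
    sample: str,
    calls: Sequence[Cdr3Call],
    counts: StageCounts,
    protein_denominator: str = "productive",
) -> RepertoireSummary:
    """Summarise one sample's CDR3 calls.

    DNA-level percentages use the number of sequences with an identified
    (non-rejected) CDR3 as denominator.  Protein-level percentages use
    the productive calls by default (``protein_denominator="productive"``)
    or all identified calls (``"identified"``).  A zero denominator is
    flagged, never silently reported as 0.
    """
    identified = [c for c in calls if c.cdr3_class is not Cdr3Class.REJECTED]
    productive = [c for c in identified if c.productive]
    n_ident = len(identified)
    counts.cdr3_identified = n_ident
    counts.productive = len(productive)

    if protein_denominator == "productive":
        prot_set, prot_n = productive, len(productive)
    elif protein_denominator == "identified":
        prot_set, prot_n = productive, n_ident
    else:
        raise ValueError(f"unknown protein_denominator {protein_denominator!r}")

    ultra_dna = sum(1 for c in identified if c.cdr3_class is Cdr3Class.ULTRALONG)
    ultra_prot = sum(1 for c in prot_set if c.cdr3_class is Cdr3Class.ULTRALONG)
    short_prot = sum(1 for c in prot_set if c.cdr3_class is Cdr3Class.SHORT)

    summary = RepertoireSummary(
        sample=sample,
        counts=counts,
        pct_ultralong_dna=Percentage(ultra_dna, n_ident),
        pct_ultralong_protein=Percentage(ultra_prot, prot_n),
        pct_short_protein=Percentage(short_prot, prot_n),
    )
    if n_ident == 0:
        summary.flags.append("no CDR3-identified sequences: DNA percentages undefined")
    if prot_n == 0:
        summary.flags.append("zero protein denominator: protein percentages undefined")
    counts.validate()
    return summary


def mean_sem(values: Sequence[float]) -> tuple[float, float | None]:
    """Arithmetic mean and standard error of the mean (sample sd / sqrt(n)).

    With fewer than two values the SEM is undefined and returned as None.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mean_sem requires at least one value")
    mean = float(arr.mean())
    if arr.size < 2:
        return mean, None
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size))
    return mean, sem


@dataclass(frozen=True)
class PairedDesign:
    """Per-cow (blood, colostrum) value pairs for one isotype and metric."""

    cow_ids: tuple[str, ...]
    blood: tuple[float, ...]
    colostrum: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.cow_ids)
        if not (len(self.blood) == len(self.colostrum) == n):
            raise ValueError("paired design requires complete (blood, colostrum) pairs")
        if n < 1:
            raise ValueError("paired design requires at least one pair")

    @property
    def n(self) -> int:
        return len(self.cow_ids)

    def differences(self) -> np.ndarray:
        return np.asarray(self.colostrum, dtype=float) - np.asarray(self.blood, dtype=float)


def wilcoxon_signed_rank_exact(design: PairedDesign) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test for a paired design.

    Zero differences are dropped before ranking (the classical
    prescription) and tied absolute differences receive midranks.  The
    statistic is ``W = min(W+, W-)``; the p-value is exact, obtained by
    enumerating all ``2^m`` sign assignments of the m nonzero
    differences and counting those whose min rank-sum is at most the
    observed one.

    Raises
    ------
    ValueError
        If every difference is zero (test undefined) or m exceeds the
        enumeration limit of 20 pairs.
    """
    diffs = design.differences()
    diffs = diffs[diffs != 0.0]
    m = diffs.size
    if m == 0:
        raise ValueError("all paired differences are zero: test undefined")
    if m > 20:
        raise ValueError(f"exact enumeration limited to 20 nonzero pairs, got {m}")
    ranks = rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    w_minus = float(ranks[diffs < 0].sum())
    w_obs = min(w_plus, w_minus)
    total = float(ranks.sum())
    # vectorised enumeration of all sign assignments
    signs = np.array(list(itertools.product((0.0, 1.0), repeat=m)))
    pos_sums = signs @ ranks
    mins = np.minimum(pos_sums, total - pos_sums)
    p = float(np.count_nonzero(mins <= w_obs + 1e-12) / signs.shape[0])
    return w_obs, p


def pearson_correlation(design: PairedDesign) -> float:
    """Product-moment correlation between the blood and colostrum sides."""
    if design.n < 3:
        raise ValueError("correlation requires at least 3 pairs")
    x = np.asarray(design.blood, dtype=float)
    y = np.asarray(design.colostrum, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance on one side: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def spearman_correlation(design: PairedDesign) -> float:
    """Rank-based correlation option (not used for the headline results)."""
    if design.n < 3:
        raise ValueError("correlation requires at least 3 pairs")
    rx = rankdata(design.blood)
    ry = rankdata(design.colostrum)
    return float(np.corrcoef(rx, ry)[0, 1])


def summarize_gene_usage(
    assignments: pd.DataFrame,
    gene_column: str = "v_gene",
    sample_column: str = "sample",
) -> pd.DataFrame:
    """Per-sample gene-usage percentages from an external assignment table.

    ``assignments`` needs a read id column, a sample column, and a gene
    label column; rows with a missing/empty gene label are excluded from
    the denominator (their count is reported in the ``n_unassigned``
    attribute of the result).  Returns a tidy frame with columns
    ``sample, gene, n, pct`` plus a cross-sample mean per gene.
    """
    if assignments.empty:
        raise ValueError("empty assignment table: nothing to summarise")
    df = assignments.copy()
    unassigned_mask = df[gene_column].isna() | (df[gene_column].astype(str).str.strip() == "")
    n_unassigned = int(unassigned_mask.sum())
    df = df[~unassigned_mask]
    if df.empty:
        raise ValueError("assignment table contains no assigned reads")
    rows = []
    for sample, grp in df.groupby(sample_column, sort=True):
        denom = len(grp)
        for gene, n in grp[gene_column].value_counts().items():
            rows.append({
                "sample": sample, "gene": gene, "n": int(n),
                "pct": round_half_up(100.0 * n / denom),
            })
    out = pd.DataFrame(rows)
    means = (
        out.groupby("gene", sort=True)["pct"].mean().map(round_half_up).rename("mean_pct")
    )
    out = out.merge(means, on="gene")
    out.attrs["n_unassigned"] = n_unassigned
    return out


def paired_report(
    designs: Mapping[str, PairedDesign],
) -> pd.DataFrame:
    """Tidy results table for a set of named paired metrics.

    One row per metric with group means ± SEM, the exact Wilcoxon
    statistic and p-value, and the product-moment correlation.
    """
    rows = []
    for metric, design in designs.items():
        mean_b, sem_b = mean_sem(design.blood)
        mean_c, sem_c = mean_sem(design.colostrum)
        w, p = wilcoxon_signed_rank_exact(design)
        r = pearson_correlation(design) if design.n >= 3 else float("nan")
        rows.append({
            "metric": metric,
            "n_pairs": design.n,
            "mean_blood": round_half_up(mean_b),
            "sem_blood": None if sem_b is None else round_half_up(sem_b),
            "mean_colostrum": round_half_up(mean_c),
            "sem_colostrum": None if sem_c is None else round_half_up(sem_c),
            "wilcoxon_W": w,
            "wilcoxon_p_exact": p,
            "pearson_r": round_half_up(r),
        })
    return pd.DataFrame(rows)
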