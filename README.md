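# bovcdr3

Extraction and classification of immunoglobulin heavy-chain CDR3s from
bovine IgM/IgG long-read amplicon sequencing, plus the paired
statistics used to compare B-cell repertoires between blood and
colostrum from the same cows.

Cattle are unusual among mammals in carrying a trimodal distribution of
heavy-chain CDR3 lengths: short (≤ 10 aa), medium, and *ultralong*
(≥ 40 aa) CDR3s, the latter forming the stalk-and-knob protrusions
implicated in broad virus neutralisation. This package implements a
stepwise, mismatch-tolerant motif-filtering procedure that identifies
CDR3s directly from noisy long-read amplicons without germline
alignment, measures them, and classifies them — and ships a synthetic
amplicon generator with a ground-truth manifest so the whole method is
testable at desk scale.

## Who it is for

Immunogenetics groups sequencing bovine (or other *Bos*/*Bison*) IgH
amplicons on long-read platforms who want a transparent, config-driven
alternative to germline-alignment portals for CDR3 length repertoires,
and anyone needing a reproducible reference implementation of the
stepwise motif-filtering method.

## The method

For each isotype, reads are retained through ordered gates:

1. **Cleaning** — per-base qualified-quality gate (Phred ≥ 15 for at
   least 60 % of bases) and an inclusive isotype length window
   (IgM 700–1200 nt, IgG 200–800 nt).
2. **Forward primer** — fuzzy search for `AGATGAACCCACTGTGGACC`
   (≤ 4 substitutions), in the orientation given.
3. **Isotype motif** — IgM: `AATCACACCCGAGAGTCTTC` (≤ 4 subs) *or* the
   truncated motif `ACAGCCTCTCT` (≤ 2 subs); IgG: `CTCAGCCTCCACCACAGC`
   (≤ 3 subs).
4. **Reverse-orientation rescue** — the full cleaned set is searched
   for the literal reverse primer (IgM `TGTTTGGGGCTGAAGTCC` ≤ 4 subs,
   IgG `GCTGTGGTGGAGGCTGAG` ≤ 3 subs); hits are reverse-complemented
   into forward orientation.
5. **Merge** — union of steps 3+4 keyed by read id.

The CDR3 is then excised between the conserved FWR3/FWR4 flanks
(pre-CDR3 family exemplified by `GAGGACACGGCCACATACTACTG`, post-CDR3
family `TGGGG(C|T)CAA`). Lengths follow the IMGT convention: the
junction is measured *exclusively* between cysteine **C104** and
tryptophan **W118**, so a span of `n` nt gives `n // 3` aa; spans
≤ 3 nt or ≥ 225 nt are removed (valid CDR3s are 1–75 aa). DNA-level
classification: short ≤ 10 aa, ultralong ≥ 40 aa, medium otherwise.
The protein path translates the codon-aligned junction window
(FWR3 position 99 through FWR4 position 120) and calls a read
*productive* when the span is in frame and the window is free of stop
codons.

Per sample, the pipeline reports `% ultralong` among DNA-level
identified CDR3s and `% ultralong` / `% short` among productive
sequences, with explicit denominators. Paired blood-vs-colostrum
comparisons use mean ± SEM, an **exact** two-sided Wilcoxon
signed-rank test (full enumeration of the 2^m sign assignments, zero
differences dropped, midranks for ties), and product-moment
correlation.

## Worked example

Simulate one IgM sample (2,000 reads, realistic ~1 % error, 50 %
orientation flips, 5 % primer-free contaminants) and run the full
pipeline:

```sh
bovcdr3 simulate --n-reads 2000 --seed 11 --isotype IgM \
    --out-fastq cow1_blood_IgM.fastq --out-manifest manifest.tsv
printf 'cow\ttissue\tisotype\tfastq\ncow1\tblood\tIgM\tcow1_blood_IgM.fastq\n' > samples.tsv
bovcdr3 run samples.tsv --out-dir out --seed 11
cat out/summary.tsv
```

```
# bovcdr3 v0.1.0 config=cab6dd0cba08 seed=11
sample  cdr3_identified  productive  pct_ultralong_dna  pct_ultralong_protein  pct_short_protein  flags
cow1_blood_IgM  1574  801  7.24  4.62  6.62
```

Reading this: of 2,000 raw reads, 1,765 survived the stepwise filter
(`out/stage_counts.tsv` has the per-stage counts), 1,574 had an
identifiable CDR3, and 801 of those were productive. 7.24 % of
identified CDR3s are ultralong at the DNA level — close to the
simulator's configured 8 % mixture weight, with the shortfall caused by
the injected sequencing errors — and 4.62 % of productive protein
sequences are ultralong. The drop from 1,574 to 801 productive reads
is dominated by simulated indels breaking the reading frame, mirroring
the DNA→protein sequence loss seen on real long-read data.

The statistics layer reproduces a published paired analysis of seven
Holstein-Friesian cows sampled at calving (shipped in
`bovcdr3.study_data`):

```python
from bovcdr3 import paired_report
from bovcdr3.study_data import paired_design

print(paired_report({
    "IgM productive ultralong %": paired_design("productive_ultralong", "IgM"),
    "IgG productive ultralong %": paired_design("productive_ultralong", "IgG"),
}).to_string(index=False))
```

```
                    metric  n_pairs  mean_blood  sem_blood  mean_colostrum  sem_colostrum  wilcoxon_W  wilcoxon_p_exact  pearson_r
IgM productive ultralong %        7        4.22       0.70            8.09           1.73         2.0          0.046875       0.69
IgG productive ultralong %        7        6.61       1.11           12.98           1.98         2.0          0.046875      -0.11
```

Colostrum carries roughly twice the percentage of ultralong-CDR3
B-cell sequences as blood for both isotypes (exact two-sided
p = 6/128 ≈ 0.047 for each), with a positive blood↔colostrum
correlation for IgM (r = 0.69) and essentially none for IgG
(r = −0.11).

## What it does not do

Basecalling/demultiplexing, V/D/J germline gene *assignment*,
clonotype collapsing, and somatic-hypermutation analysis are out of
scope; externally produced assignment tables can be tabulated with
`summarize_gene_usage`. See `docs/methods.md` for model details,
parameter meanings, and known limitations.
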