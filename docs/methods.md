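# Methods

## The filtering model

The pipeline treats a CDR3 call as a pure pattern-recognition problem:
an amplicon is accepted when a fixed set of literature-derived
nucleotide motifs can be found within per-motif substitution budgets,
and the CDR3 is the sequence between two conserved flanking motifs.
No germline alignment is performed; the method's accuracy therefore
depends entirely on the conservation of the anchor motifs and on the
mismatch budgets.

**Mismatch model.** All fuzzy matching is Hamming (substitutions
only), scanning every window of pattern length and accepting distance
≤ `max_subs`. Indel-tolerant matching is deliberately rejected: the
CDR3 boundary and reading frame are computed as fixed nucleotide
offsets from motif match coordinates, which is only well defined when
the match cannot absorb or emit bases. The cost is that a sequencing
indel *inside* a motif usually loses the read (or, in the junction,
breaks the frame); that loss is visible in the DNA→protein retention
numbers and is an inherent property of the method, not an artifact of
this implementation.

**Tie-breaking.** The matcher returns the leftmost qualifying window
(not the minimum-distance window); among alternatives of an
alternation family at the same start, fewer substitutions, then the
shorter literal, win. Leftmost selection makes results deterministic
and order-independent. An `N` in a read always counts as a mismatch —
conservative, so low-quality stretches cannot fake a motif hit.
Coordinates are 0-based, half-open throughout.

## Boundary arithmetic

The pre-CDR3 exemplar `GAGGACACGGCCACATACTACTG` ends two bases into
the conserved C104 codon (the `TG` of `TGT`/`TGC`), so the CDR3 starts
one base after the match end (`cdr3_boundary_offset = +1`), and the
match start is codon-aligned (`frame_offset = 0`). The post-CDR3
family `TGGGG(C|T)CAA` opens with the W118 codon `TGG`, so the CDR3
ends exactly at the match start. Measured this way the junction
excludes both C104 and W118, and the 225-nt span cap corresponds to
the 75-aa upper bound on a plausible CDR3.

The junction is located as: leftmost pre-CDR3 hit, then the *nearest*
post-CDR3 hit downstream whose implied span is under 225 nt. The
proximity rule matters because FWR4-like motifs recur in the constant
region much further downstream; accepting the nearest sub-cap hit
rejects those. When post hits exist but all imply ≥ 225 nt, the read
is a no-call and is excluded from the CDR3-identified denominator.

**DNA vs protein level.** DNA-level classification uses
`aa_len = nt_len // 3` with no frame requirement, because repertoire
percentages at the DNA level intentionally include out-of-frame reads.
The productive path additionally requires `nt_len % 3 == 0` and a
stop-free translation of the codon-aligned window from the pre-CDR3
match start through the end of the post-CDR3 match (FWR3 ≈ position 99
through FWR4 position 120). A codon containing `N` translates as `X`
and does not destroy productivity; only bona fide TAA/TAG/TGA do.

**A boundary wrinkle.** Short CDR3s are defined as ≤ 10 aa, nominally
including 1 aa, but the removal rule drops spans ≤ 3 nt — and a 1-aa
CDR3 is exactly 3 nt. Both rules are kept as stated, so a 1-aa CDR3
is always class `rejected`. The synthetic generator may still emit
1-aa CDR3s (the short-class sampler starts at 1 aa); their lengths are
recovered correctly but they never appear in the identified
denominator.

## Thresholds and defaults

| parameter | default | meaning |
|---|---|---|
| `min_qual` | 15 | per-base qualified-quality Phred threshold |
| `max_unqualified_fraction` | 0.40 | max fraction of bases below `min_qual` |
| length window IgM | [700, 1200] nt | inclusive cleaning window |
| length window IgG | [200, 800] nt | inclusive cleaning window |
| forward primer budget | 4 subs | `AGATGAACCCACTGTGGACC` |
| IgM motif budgets | 4 / 2 subs | long / truncated motif (logical OR) |
| IgG motif budget | 3 subs | `CTCAGCCTCCACCACAGC` |
| reverse primer budgets | 4 (IgM) / 3 (IgG) | literal search, then revcomp |
| pre-CDR3 budget | 2 subs | family exemplar, offset +1 nt |
| post-CDR3 budget | 1 sub | `TGGGG(C|T)CAA`, offset 0 |
| CDR3 span | 4–224 nt kept | ≤ 3 nt and ≥ 225 nt rejected |
| short / ultralong | ≤ 10 aa / ≥ 40 aa | DNA- and protein-level classes |

The quality gate encodes the documented defaults of the standard
FASTQ cleaner (qualified quality 15, at most 40 % unqualified bases)
rather than shelling out to it, keeping the gate reproducible and
configurable. The exact pre/post-CDR3 motif families in field use are
curated from germline V/J references and are not uniquely fixed;
here they ship as an editable config (`bovcdr3 config`) with a
single-exemplar pre family (budget 2) and a two-literal post family.
All synthetic-data results use these shipped defaults.

Step 4 (reverse rescue) does not re-check the isotype motif after
re-orientation, matching the direct merge of the original procedure;
`recheck_isotype_after_reorient: true` enables a stricter run.
Deduplication is keyed on read id — the duplicates being removed are
the same read reaching the merge through both branches. A read
matching both a forward primer and a literal reverse primer (possible
chimera) keeps its step-2, as-given copy; chimera flagging is not
implemented.

## Paired statistics

* **mean ± SEM** — SEM is the sample standard deviation (n−1) over
  √n; undefined (not 0) for n < 2.
* **Exact Wilcoxon signed-rank** — zero differences dropped before
  ranking (the classical prescription), midranks for tied absolute
  differences, statistic `W = min(W+, W−)`. The two-sided p-value is
  exact: all 2^m sign assignments are enumerated and those whose
  min rank-sum is ≤ the observed one are counted. Enumeration is
  capped at m = 20 (beyond that the vectorised table would exceed
  memory; the study design here has m = 7). Note that large-sample
  software approximations give slightly different p-values
  (e.g. 0.048 where the exact value is 6/128 = 0.046875); this
  package always reports the exact value.
* **Correlation** — product-moment (Pearson) by default, which is
  what the reference analysis used; a Spearman option exists but is
  not used for any headline number.
* **Rounding** — half-up to 2 decimal places, applied only at the
  reporting layer; all internal arithmetic is full precision.
* **Gene usage** — per-sample percentages over externally assigned
  reads only; unassigned reads are excluded from the denominator and
  their count reported. Gene *assignment* is out of scope.

Zero denominators anywhere (empty sample, no productive reads)
produce flagged, undefined percentages — never a silent 0.

## The synthetic amplicon generator

Templates follow the amplicon architecture end to end: forward primer,
fixed pseudo-germline FWR1–3 scaffold, pre-CDR3 motif + C104
completion base, CDR3 of requested aa length from random stop-free
codons, post-CDR3 motif, fixed FWR4/constant filler, isotype motif,
and the reverse complement of the reverse primer. Scaffold length is
auto-adjusted so totals sit mid-window (900 nt IgM, 450 nt IgG).
Defaults: class mixture 0.05/0.87/0.08 (short/medium/ultralong) with
uniform aa lengths 1–10 / 11–39 / 40–70, 50 % orientation flips, 20 %
non-productive reads (one injected in-frame stop), 5 % primer-free
random contaminants.

**Unambiguity by construction.** Because the CDR3 is random sequence,
it can by chance contain a fuzzy pre/post-motif hit that would shift
the located junction, or its reverse complement can contain spurious
primer hits. A candidate template is therefore rejected and its CDR3
re-drawn until (a) the shipped default motifs locate exactly the
constructed junction and (b) the reverse-complemented template cannot
be captured in the wrong orientation. This is what makes the
manifest an exact oracle on error-free data: the 100 %-recovery and
orientation-invariance test properties are properties of the method
*given unambiguous anchors*, and the generator guarantees the
anchors are unambiguous.

**Error model.** Independent per-base substitutions (default 0.005),
insertions (0.0025) and deletions (0.0025) — a deliberately simple
~1 % profile that exercises the mismatch budgets and frame logic; no
attempt is made to imitate homopolymer-biased long-read error
spectra, quality/error correlation, chimeras, or somatic
hypermutation. Qualities are Gaussian (mean 20, sd 6, clipped to
[2, 41]) and independent of the injected errors. Template
construction, error injection, and quality drawing use three
independent RNG streams derived from the seed, so runs differing only
in error rates share identical templates; same seed + config is
byte-identical.

Consequently, passing tests demonstrate correctness of the *method
mechanics* (gating, orientation handling, boundary arithmetic, frame
and stop logic, denominators) — not performance on real instrument
data, whose error structure, primer artifacts, and template diversity
the generator does not emulate.

## Problem sizes used in the test suite

The large synthetic checks run 20,000 reads (IgG geometry, error-free,
fixed seed) through the whole pipeline — large enough that the
binomial 3-SE band on the 8 % ultralong mixture weight is ± 0.6
percentage points — and 2,000 reads for the orientation-invariance
comparison; both finish in well under a minute on one core. The
matcher is verified against a brute-force Hamming scan exhaustively on
tiny instances and on 500 seeded random instances.

## Known limitations

* Motif families are a shipped default, not the (unpublished) exact
  regular expressions of any particular laboratory run; real-data
  results depend on curating these for the germline background in use.
* Hamming-only matching loses reads with indels inside anchor motifs;
  on long-read data this biases retention toward lower-error reads.
* The exact Wilcoxon path enumerates 2^m assignments and is for small
  paired designs (m ≤ 20).
* No chimera detection; a read carrying both orientations' primers is
  treated as its as-given copy.
* Gene-usage tabulation trusts the external assignment table verbatim.
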