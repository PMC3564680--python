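# Methods

This note documents the models, rules and numerical choices behind each
pipeline stage, what the synthetic-data generator does and does not
emulate, and the design decisions taken where published small-RNA
pipelines leave details unstated.

## Read cleaning

Raw small-RNA reads are single-end sequences that run through an 18–32 nt
insert into the 3' sequencing adapter. The cascade assigns each read to
exactly one category, in a fixed order chosen so the categories partition
the library and the clean count follows by subtraction:

low-quality → 3'adapter_null → insert_null → 5'adapter_contaminant →
smaller_than_18nt → polyA → clean.

Published accounting tables state category counts but not the detection
rules, so the rules here are explicit and configurable:

* **low-quality**: any base below Q20 (Phred+33) or any N. Q20 is the
  common "high-quality read" floor; reads failing it are excluded from
  the high-quality denominator that all percentages use.
* **3'-adapter**: leftmost position where a prefix of the 3' adapter
  (≥ 6 nt, ≤ 1 substitution) matches; no match → `3'adapter_null`.
  Six exact-ish bases keep the false-trigger rate of a random 30-mer
  below ~10⁻², and one tolerated substitution covers sequencing error in
  the adapter itself.
* **insert_null**: empty insert after trimming, or an insert equal to the
  5' adapter (adapter dimer).
* **5'-adapter contaminant**: insert starting with the first 10 nt of the
  5' adapter (≤ 1 substitution) — a read-through ligation artifact. Ten
  bases make the chance of flagging a genuine insert ≈ 3 × 10⁻⁵.
* **smaller_than_18nt**: insert shorter than `min_len` after trimming
  (assessed after the 3'-trim; the insert length is undefined before it).
* **polyA**: insert with ≥ 90% adenine.

An upper length cap is applied only when configured; by default inserts
longer than 32 nt are retained as clean, since real libraries report reads
up to 32 nt even when gels selected a narrower range.

## Unique tags, classification, mapping

Identical clean tags collapse into one record with a per-library count
vector. Classification against contaminant references uses exact substring
membership (fragments of rRNA/tRNA/… are degradation products of their
source molecules) with a fixed precedence (rRNA > tRNA > snRNA > snoRNA >
repeat > mRNA); the first matching class wins, making classification a
partition.

Genome mapping reports *all* loci on either strand within 2 substitutions,
no gaps. The scanner splits the query into `max_mismatches + 1` contiguous
chunks; by pigeonhole, any admissible window matches one chunk exactly, so
locating exact chunk occurrences and verifying the full window by Hamming
count is complete — the tests compare it against a literal sliding-window
scan. Multi-mapping tags keep all hits and counts are not split; each hit
is considered independently downstream.

## Conserved miRNA assignment

A tag is compared to each mature reference with a global alignment whose
terminal gaps (up to 2 nt per end) are free — miRNA 5'/3' length variants
are ubiquitous — and whose costs are: non-wobble substitution 1.0,
wobble-class substitution (A↔G, C↔U, the transitions that preserve G:U
pairing potential) 0.5, internal gap 2.0. A tag is assigned to its best
reference if (i) mismatches (non-wobble substitutions + gaps) ≤ 2,
(ii) weighted score ≤ 4.5, and (iii) total non-identical positions ≤ 2.
Constraint (iii) is what "near perfectly matched" means operationally:
without it, a deeply sequenced random background occasionally reaches the
score threshold through wobble-heavy alignments (≈ 2 × 10⁻⁴ per random
tag against 50 references), which would contaminate the catalogue; with
it the false-assignment probability drops below 10⁻⁶ while every ≤ 2-
substitution variant of a true miRNA still passes. Ties break to the
lexicographically smallest reference id.

A shared-6-mer prefilter skips references that cannot be within 2 edits
(two interior edit breakpoints in ≥ 16 aligned nt leave an exact run of
≥ 6), so the prefilter is lossless; the tests verify it against
exhaustive scoring. Families are parsed from reference ids (`miR(\d+)`).

## Folding and novel miRNA prediction

Folding sits behind one contract with two engines. The default delegates
to the ViennaRNA nearest-neighbour thermodynamic model when the `RNA`
bindings are importable. The built-in alternative is a stacking-energy
Nussinov variant — pair energies GC −2.0, AU −1.5, GU −1.0 kcal/mol, +3.0
per hairpin loop, minimum loop 3 — whose optima are checkable by
exhaustive enumeration on small instances. Energies from the two engines
are not interchangeable numerically; all thresholds below were chosen for
and tested with the default engine.

For each genome hit of an unannotated tag with total count ≥ 5, a window
of ±150 nt is folded (reverse-complemented for minus-strand hits so the
tag reads 5'→3'). Acceptance requires: ≥ 16 tag bases paired and ≤ 4
unpaired; all pairing partners on one side of the tag (the arm test — a
read spanning the loop is not a mature miRNA); no asymmetric bulge > 2 nt
inside the duplex; weighted score of the tag against the reverse
complement of its partner segment ≤ 5.0; and precursor MFE ≤ −18 kcal/mol.
The precursor is delimited by walking the enclosing stem outward from the
duplex until the helix breaks into a multiloop (> 8 nt jump on either
side), then folded on its own for the reported energy and structure —
folding the whole ±150 window would make the energy threshold vacuous,
since any 300-nt window folds well below −18 kcal/mol.

A hairpin is an inverted repeat, so a mature tag maps to *both* strands of
its own precursor; overlapping candidate loci on a scaffold are therefore
merged regardless of strand, each tag contributing its counts once. The
most abundant tag at a locus provides the mature sequence; a partner-arm
tag within ±2 nt of the canonical miRNA\* position (2-nt 3' overhangs) is
reported as the star. Accepted candidates are numbered `oeu_mir_N` in
locus order and serialised with 1-based inclusive `scaffold:start:end`
locations and per-library 5p/3p count columns.

## Quantification and enrichment

TPM is `count / library_clean_total × 10⁶`, exactly, with no
pseudo-counts, so a complete library sums to 10⁶. Fold changes are TPM
ratios; when either count is zero, 0.5 raw reads (converted to each
library's own TPM scale) are added to both sides, and 0-vs-0 is defined as
1.0 — this leaves every nonzero comparison untouched. Enrichment is the
one-sided hypergeometric upper tail per term over a user-supplied
gene → term map; Benjamini–Hochberg q-values are reported alongside, with
the significance flag on raw p < α by default (the common convention for
this analysis), switchable to q.

## Target prediction

Duplex positions are numbered 1..L from the miRNA 5' end; states are
match / G:U wobble / mismatch / gap with weights 0 / 0.5 / 1 / 2. The six
criteria: (i) total weight ≤ 4; (ii) no run of ≥ 3 mismatch/gap states;
(iii) no run of ≥ 2 mismatch/gap states within positions 2–12;
(iv) positions 10–11 perfectly paired — a wobble counts toward the
mismatch total, so it is not "no mismatch" and is disallowed at the
cleavage site; (v) total weight over positions 1–12 ≤ 2.5; (vi) duplex
MFE ≥ 75% of the miRNA/perfect-complement MFE, both computed with the
same engine so model constants cancel.

The scan evaluates the gapless antiparallel alignment at every offset of
every transcript. No seeding heuristic is used: a seed requiring exact
pairing anywhere would wrongly drop sites that criteria i–v still admit,
and gapped extensions buy almost nothing against a 2.0 gap weight under
the 2.5 budget in positions 1–12 — so the default scan is exhaustive and
gapless, and *is* the brute-force reference it is tested against. Gap
states remain supported when scoring externally constructed alignments.
The energy ratio is only computed for sites that already pass the
sequence criteria, which cannot change the accepted set.

## Synthetic data and what passing tests mean

The generator emulates a six-library experiment (UF/RF fruit, JON/NON/
JOFF/NOFF leaf labels): fixed-length 49-nt reads of the form
`insert + 3'adapter + fill`, artifact categories at configurable
fractions (defaults of a few parts per thousand, the magnitudes deep
small-RNA runs report), an 18–32 nt insert length distribution with the
24-nt mode typical of plant libraries, planted known miRNAs with
log-normal library-specific abundances plus fixed 1- and 2-substitution
variants, planted perfect-stem hairpin loci (mature on the 5' arm, star
with 2-nt 3' overhang) embedded in a random genome, per-class contaminant
fragments, genome-derived background, and purely random background.
Every read gets exactly one ground-truth label and manifests tally
realized counts exactly, so cleaning is tested for equality, not
approximately.

Inserts are rejection-sampled so they cannot trigger adapter detection
(no 5-window within one mismatch of the 3'-adapter start — this also
covers windows straddling the insert/adapter junction — and no 10-window
matching the 5'-adapter probe). This is what makes manifest-equality
testing possible, and it is also the generator's main departure from real
data, along with: no sequencing-error model, no PCR duplication,
constant quality strings, perfect hairpin stems, and contaminants that
are literal substrings of their references. Passing tests therefore
demonstrate the *correctness of the accounting, matching, folding and
rule logic* under clean conditions, not robustness to sequencing noise or
to the imperfect hairpins of real genomes.

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical configurations are byte-identical.

## Problem sizes and defaults

The generator defaults to 10⁵ reads per library, 50 known miRNAs,
10 hairpin loci and 20 contaminants per class. The verification scripts
use: one 10⁵-read library for TPM conservation; six libraries totalling
10⁵ reads for conserved-miRNA recovery; and twenty independent 100-kb
genomes with 10 loci each (two 5 000-read libraries per genome — enough
to put every locus above the count-5 threshold with high probability) for
novel-locus recovery. These sizes were chosen as the smallest at which
the binomial noise of the planted abundances is negligible relative to
the quantities being checked.

## Known limitations

* The built-in folding model ignores loop-size dependence and dangling
  ends; it is a structural plausibility model, not thermodynamics.
* Hamming-only genome mapping (no indels), as in short-read seed tools.
* Counts of multi-mapping tags are duplicated per locus rather than
  fractionally assigned.
* The target scan is O(transcripts × offsets × L); fine for EST-scale
  sets, not for whole transcriptomes at miRBase scale.
* Star detection requires the star tag itself to have been sequenced at
  or above the count threshold.
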