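# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Differential screen

Per transcript the two groups are compared with an unpaired two-sided
*t*-test. The Welch (unequal-variance) form is the default because it is
the robust choice when group variances are unknown; the pooled-variance
form is available via `equal_var=True`. Degenerate inputs follow fixed
conventions: two identical constant groups give (t=0, p=1); two unequal
constant groups are an infinitely confident separation and give p=0 with
a `RuntimeWarning`.

Fold change is always a linear case/control mean ratio (log2-stored
matrices are back-transformed first) with the signed convention
r ↦ −1/r below 1, so down-regulation prints as a negative multiple —
the convention used in published differential tables. The screen's gates
are strict: *P* < 0.05 and |FC| > 2; a transcript at exactly 2.0 fails.
No multiple-testing correction enters the gate (the workflow this
reimplements filters on raw *P*); a Benjamini–Hochberg q-value column is
emitted for information only.

## Target determination

The seed is defined as miRNA positions 2–8 (1-based, 5'→3'), the
canonical 7-mer; a site is an exact Watson–Crick reverse-complementary
transcript window, no G:U wobble, all overlapping occurrences reported,
coordinates 1-based on the sense strand. Site typing (8mer/7mer-A1),
3'-supplementary pairing and conservation are deliberately out of scope.

The duplex energy is a small explicit surrogate for hybridization tools
like RNAhybrid, not a reimplementation of them. Model: an antiparallel
alignment of the two strands scores the sum of stack energies — each
adjacent base-pair stack contributes the mean of its two per-pair
energies (G:C −3.0, A:U −2.0, G:U −1.0 kcal/mol) — plus an affine
penalty per interior loop/bulge (+4.0 to open, +0.5 per unpaired
nucleotide); lone pairs and dangling ends are free; intramolecular
structure is ignored. The minimum over all alignments is computed by a
two-state O(nm) dynamic program and equals exhaustive alignment
enumeration (verified on random inputs up to length 10). The energy is
invariant under strand swap and under reversing both strands; exact
invariance under joint reverse-complement holds only when no G:U pair
can form, since the complement of a wobble pair is not a pair.

A predicted miRNA–lncRNA pair requires at least one seed site whose
duplex energy over the site ±10 nt of flank is ≤ −20 kcal/mol. The −20
default is configurable; it sits between "seed-only" duplexes (≈ −13 to
−16 under this model) and extended complementarity, so it keeps sites
with some 3' support and discards bare chance seed matches.
miRNA–mRNA pairs are not predicted but loaded from interaction tables,
de-duplicated with provenance retained, mirroring the use of curated
databases for coding targets.

## Coexpression and triplet assembly

Pearson correlation p-values use the exact t transform
t = r√((n−2)/(1−r²)) with n−2 degrees of freedom; |r| = 1 maps to p = 0
and constant vectors are reported NaN and excluded by every strict gate.
The lncRNA–mRNA coexpression gate is one-sided (r > 0.99, p < 0.05, both
strict): competing partners co-rise, so anticorrelated pairs do not
qualify. A triplet requires the shared miRNA to be negatively correlated
with both partners; only the signs are gated by default (a significance
gate is available via `require_negative_p`), matching the minimal
published rule. Assembly is exhaustive over all candidate combinations
and returns a deterministically sorted list.

## Topology

The hub threshold is degree ≥ 5, not > 5: the published hub table that
serves as the worked example itself lists degree-5 nodes as hubs, so the
inclusive reading is taken and the threshold left configurable. Note the
reference tables are internally inconsistent for one lncRNA
(NONHSAT033305: degree 5 in the hub table, 4 first-order pairs in the
pair-count table) and attach the 358-edge subnetwork to a different
lncRNA than the pair-count total of 320 would suggest; the tables are
shipped verbatim and the pair-count arithmetic is trusted as printed.

Second-order pairs count each mi–m edge once per incident selected
miRNA with no global de-duplication — this is what makes the identity
"subnetwork edge count = first + second pairs" hold exactly, and it
matches the printed pair-count arithmetic. Key-lncRNA ranking sorts by
(first pairs desc, total desc, id asc); k = 3 by default. Ties are
broken lexicographically so the ranking is stable under row reordering.

## Enrichment

One-sided hypergeometric upper tail (equivalent to one-sided Fisher),
computed via scipy's survival function (log-space stable far beyond the
N ≤ 10⁵ regime used here) and verified against direct combinatorial
summation for every configuration with N ≤ 12. The universe defaults to
the measured mRNAs rather than the genome, the correct background for
array-derived queries. Terms with zero overlap are suppressed; "enriched
term counts" use raw p < 0.05; BH q-values are reported alongside. Flat
sets only — no GO-hierarchy propagation, no pathway topology.

## Synthetic data generator

The generator emulates a two-group normalized expression study (the
values are emitted already normalized; no background correction, probe
collapsing, batch effects or PCR-array-specific noise are modelled) with
planted ceRNA structure:

* Expression is simulated on the log2 scale: per-transcript baseline
  N(8, 1), i.i.d. Gaussian noise (σ = 0.1 by default), and a
  between-group shift of ±log2(fc_planted) for planted DE transcripts
  (default fold change 4). Each planted triplet owns a per-sample latent
  factor loading +coupling on its lncRNA and mRNA and −coupling on its
  miRNA (default 0.95). The factor-only expected correlation is
  coupling²/(coupling²+σ²) ≈ 0.989; adding the shared DE shift
  (d = log2 4 = 2, balanced groups contribute d²/4 to the covariance)
  gives (d²/4 + c²)/(d²/4 + c² + σ²) ≈ 0.995 for within-triplet
  lncRNA–mRNA pairs — deliberately above the strict 0.99 gate, because
  the pipeline's own threshold defines what "planted to be recoverable"
  must mean. Orientation (up or down in cases) is drawn per miRNA so
  triplets sharing a miRNA never receive contradictory directions.
* A decoy fraction (10% per class) of non-triplet transcripts is DE in
  random directions, and decoy interaction-table rows (60 by default)
  pair random miRNA/mRNA combinations, so precision is measured against
  genuine distractors. Cross-triplet lncRNA–mRNA pairs cannot pass the
  0.99 gate because each triplet's unit-variance latent factor
  decorrelates them (r ≈ 0.5), which is what keeps assembly precision
  high without any tuned filtering.
* Sequences: miRNAs 19–24 nt, lncRNAs ≥ 200 nt (default 300, matching
  the defining length threshold for lncRNAs), uniform random background.
  Each planted site embeds the reverse complement of miRNA positions
  1..site_length (default 14) at a recorded position, which guarantees
  the seed match and a duplex energy ≤ −26 kcal/mol even in the all-A:U
  worst case — planted sites clear the −20 gate by construction, while
  chance background sites mostly do not.
* Gene sets: n_terms (default 50) sets over the mRNA universe with
  sizes 10–40; a few terms (default 5) sample triplet mRNAs with 10×
  boosted probability. boost = 1 removes the structure and is the null
  calibration case.

All randomness flows from one integer seed through fixed-purpose
`numpy.random.SeedSequence` streams, so matrices, FASTA, tables, GMT and
ground-truth JSON are byte-identical across re-runs.

What passing recovery tests show — and do not show: they demonstrate the
pipeline's gates are mutually consistent and recover exactly the
structure they define, under Gaussian noise and a single latent factor
per triplet. Real array data add correlated noise, batch structure,
heavier tails and annotation error, none of which are emulated; recovery
rates here are upper bounds, not field performance estimates.

## Problem sizes and defaults

The default regime is 20+20 samples, 80 lncRNAs, 24 miRNAs, 160 mRNAs,
20 planted triplets — a deliberately desk-scale study in which every
stage (including all-pairs duplex scoring) runs in seconds while leaving
room for decoys at roughly the planted:background ratio of a filtered
array experiment. The headline validation in `scripts/acceptance.py`
uses this regime plus 20 gene-set replicates at a 1000-gene universe.
Config validation permits fc_planted = 1 (a pure null) even though any
screenable planting requires fc_planted > 2; the null case exists for
calibration tests.

## Known limitations

* The duplex model's absolute energies are not comparable to RNAhybrid
  or miRanda outputs; only orderings and thresholds within this model
  are meaningful.
* The triplet rule is correlation-based; no partial-correlation or
  sensitivity-correlation ceRNA scoring is provided.
* Degree is the only centrality; hub calling inherits its threshold's
  arbitrariness.
* Enrichment ignores term hierarchy and inter-term overlap.
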