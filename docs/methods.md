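# Methods

This note records the models, parameter choices and numerical conventions
behind the toolkit, and what the synthetic experiments do and do not show.

## Coordinates

All internal coordinates are 0-based half-open.  BLAST tabular and GFF3 are
1-based inclusive and are converted exactly once, at the format boundary in
`io_formats`.  On the BLAST subject side, `sstart > send` marks a
minus-strand alignment and normalizes to the interval
`[min−1, max)` with strand `−`; the interval length therefore always equals
`|send − sstart| + 1`.

## Hit filtering and locus building

* **Thresholds.**  Alignment length is filtered strictly (`> 100 bp`) and
  identity inclusively (`≥ 85%`).  The asymmetry is deliberate: "greater
  than" versus "minimum" name different comparison operators, and both are
  exposed as parameters.
* **Nested-hit removal** keeps only hits not contained in another hit's
  scaffold interval, evaluated per scaffold and ignoring the organelle
  label (a mitochondrial fragment inside a longer plastid hit adds no
  independent evidence).  Among byte-identical intervals exactly one
  survives: highest bitscore, then highest identity, then earliest input
  position.  Partial overlaps are kept at the hit stage and resolved by
  merging — only true containment is pruned.  The implementation is a sort
  + sweep (O(n log n)); tests compare it against an O(n²) brute-force
  oracle on a thousand random inputs.
* **Merging.**  Hits on one scaffold that overlap or lie within `max_gap`
  bp (default 500) are transitively grouped; the locus interval is the
  hull.  500 bp bridges alignment breaks inside one biological insertion
  (indels, diverged stretches splitting a single transfer into several
  hits) without fusing independent insertions, which the generator places
  kilobases apart; no published merge distance exists for this step, so the
  parameter is configurable and tests assert monotonicity (more gap, never
  more loci) rather than a specific value.
* **Locus identity** is the alignment-length-weighted mean of member-hit
  identities (an unweighted option exists).  Weighting by length makes the
  locus value an estimate of per-base identity rather than per-hit, which
  is what the divergence interpretation needs.
* A locus is classified NUMPT exactly when its member hits carry both
  organelle labels.

## Junction confirmation

A locus has up to two testable junctions: its boundaries, minus any
boundary coinciding with a scaffold terminus (no nuclear flank exists
there, so nothing can span it).  A read supports a junction when a
contiguously aligned reference block covers the window
`[junction − 20, junction + 20)`:

* 20 bp overhang separates genuine spanning from terminal micro-overlaps,
  where a few matching bases at a read end could align across the boundary
  by chance;
* soft/hard-clipped bases contribute nothing — clipping at the junction is
  precisely the artifact signature;
* internal deletions ≤ 5 bp inside the window are tolerated as indel
  sequencing error; longer deletions and reference skips break contiguity;
* records must be primary, mapped, and at MAPQ ≥ 20 (default).

Status: *untested* when no junction is testable; otherwise *confirmed* iff
every testable junction (default; `any` mode available) has ≥ 1 spanning
read.  One read suffices by default because the operational definition of
an unconfirmed locus is "no overlap reads at all"; the threshold is
configurable upward for noisier data.  The statuses partition the loci by
construction.

`confirm_loci_sam` streams the SAM once, assigning each alignment to the
junction windows it overlaps (windows sorted per scaffold, binary search on
read span); it is tested for exact agreement with the per-locus in-memory
path.

The identity comparison between statuses is a one-way fixed-effects ANOVA
(`scipy.stats.f_oneway` behind the interface), with group means and both
degrees of freedom reported.  Inputs with fewer than two groups, a group of
fewer than two values, or zero within-group variance are rejected as
untestable.  Tests verify agreement with brute-force sums of squares to
1e-10 relative error and the two-group identity F = t².

## Entropy screen

For a contig of length L and k-mer size k, all L−k+1 overlapping windows
are counted (windows containing N are skipped — N is missing data, not a
fifth symbol) and H = −Σ pᵢ log₂ pᵢ is computed from the empirical
distribution.  The attainable maximum is min(2k, log₂ #windows): 2k bits
caps the alphabet, log₂ #windows caps what finitely many windows can show,
and normalizing by it prevents short contigs from being flagged merely for
being short.  Defaults k = 5 and normalized-entropy threshold 0.3 were
chosen so that mono-, di- and tri-nucleotide repeats are flagged
(normalized entropy ≤ 0.16 at k = 5) while uniform-random sequence sits
near 0.96; both are exposed on the API and CLI.  Contigs under 1,000 bp are
excluded before any entropy is computed.

## Annotation statistics

* **Transposon filter.**  The default term list is the fourteen
  transposon-related description terms used for this purpose in plant
  genome annotation (transcriptase, transposase, gag, env, transposon,
  repetitive element, RNA-directed DNA polymerase, pol protein, non-LTR
  retrotransposon, mobile element, retroelement, retrovirus, Retroviral,
  group-specific antigen).  Matching is case-insensitive substring, except
  that terms shorter than five characters (gag, env) must match as whole
  tokens at word boundaries — otherwise "env" fires inside "envelope"-like
  words.  A gene is flagged iff matching domains strictly exceed half of
  its domains; zero-domain genes are never flagged.
* **Support filter.**  A gene is removed iff it has no external support
  (transcript or protein alignment evidence) *and* no functional
  annotation — a conjunction, so either source of evidence rescues it.
* **z-scores.**  z = (count_focal − mean)/sd with the sample standard
  deviation (n−1) over the non-focal species.  Excluding the focal species
  from the baseline is the default because the question is how the focal
  species compares to the *others*; `include_focal=True` gives the pooled
  alternative.  With zero baseline spread, z is 0 when the focal count
  equals the mean and signed infinity otherwise (the call follows the
  sign); at least three baseline species are required for a meaningful sd.
  Calls use |z| > 1.96, the two-sided 5% normal quantile.
* **Enrichment.**  Per term, p = P(X ≥ k) for hypergeometric(N, K, n);
  Benjamini–Hochberg step-up across all tested terms; significance is
  `p_adjusted < 0.05` by default (thresholding the raw p is available,
  since "FDR-corrected" and "p < 0.05" admit both readings; adjusted is the
  conservative one).  No GO-DAG propagation is performed.

## Synthetic data model

The generator emulates exactly the features the pipeline measures:

* **Sequence model.**  Nuclear scaffolds and organelle genomes are i.i.d.
  nucleotides at a configurable G+C (default 0.361, a typical value for
  the kind of plant nuclear assembly this toolkit targets).  Insertions
  copy an organelle segment (either strand), apply i.i.d. substitutions at
  rate d — substitution-only by default so realized identity is
  analytically `100·(1 − n_sub/L)` and binomially concentrated — and
  splice it into a scaffold.  Composite (NUMPT) insertions splice one
  plastid and one mitochondrial segment adjacently, split 40–60%, so each
  part stays above the 100 bp hit-filter floor at the 300 bp minimum
  insertion length.
* **Placement.**  Insertions keep ≥ 5 kb from each other and from scaffold
  ends, so independent insertions never merge under the default 500 bp gap
  and every junction has ample nuclear flank.
* **Artifacts.**  `make_artifact_assembly` inserts additional organelle
  segments into the assembly only; the read-generating sample genome lacks
  them.  Genuine truth coordinates are lifted to assembly coordinates, and
  the sample→assembly breakpoint map is recorded.
* **Reads.**  Paired 150 bp reads at fixed 350 bp insert are placed
  uniformly at the configured coverage with i.i.d. substitution errors
  (default 0.2%), and written as a truth SAM against assembly coordinates
  at MAPQ 60.  A read whose span crosses an artifact breakpoint is
  soft-clipped at the junction, keeping the longer aligned part — the
  behaviour of a real mapper given reads from the artifact-free genome.
  Hence artifact junctions have exactly zero spanning reads by
  construction, while genuine junctions are covered like any other
  position (expected ≈ 22 spanning reads per junction at 30×).
* **Hit tables** carry exact planted coordinates and realized identities;
  optional noise injections add strictly nested sub-hits (which de-nesting
  must remove without changing the locus set) and sub-threshold rows
  (short or low-identity, which the filter must drop).
* **Determinism.**  Every stage draws from `numpy.random.default_rng`
  seeded with `[seed, stage_index]`, so outputs are byte-identical across
  runs and stages are independently reproducible.

**What passing these tests does and does not show.**  The generator's
i.i.d. sequence model contains no repeats, no heterozygosity, no
mapping ambiguity and no indel error, so recovery here demonstrates the
correctness of the bookkeeping and the discriminating logic — not the
field performance of a mapper on repeat-rich plant genomes.  In real data,
organellar insertions inside transposon-dense regions can lose junction
support through MAPQ filtering, which would move genuine loci from
confirmed to unconfirmed; the thresholds exist to navigate exactly that
trade-off.

## Experiment sizes

The standard recovery experiment uses 3 × 1 Mb scaffolds, 30 genuine
insertions (10 NUPT, 10 NUMT, 10 NUMPT; 300–3,000 bp; 2–10% divergence),
10 artifacts and 30× paired reads (~300k pairs) — large enough that every
class, both junction sides, clipping and liftover are all exercised, while
a full run (simulation, detection, read generation, confirmation) completes
in seconds.  The identity-direction experiment plants genuine insertions at
4–10% divergence (mean 7%) versus artifacts at 1–5% (mean 3%) on
2 × 300 kb scaffolds.

## Known limitations

* The junction test consumes alignments, not reads: mapping itself is out
  of scope, and the truth SAM stands in for a mapper in all tests.
* No indel mutation model for insertions (available as a non-goal; the
  substitution-only model keeps identities exactly predictable).
* Hit tables are taken as given; the toolkit does not run the homology
  search (the search program, task and e-value cutoff are upstream
  choices).
* Simple-repeat flagging depends on k and the threshold; the defaults are
  justified above but no claim is made that they reproduce any particular
  historical contig count.
* Loci at scaffold termini are testable on their single interior junction;
  a locus spanning an entire scaffold is untestable and reported as such.
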