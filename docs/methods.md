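# Methods

## The model

A *strain genome space* is the collective of closely related genomes —
a consensus plus its sub-populations — treated as one entity.  The
package's first-order model permits only SNPs and small indels between
sub-populations (no rearrangements; see Limitations).  Its coordinate
system is the gapped consensus: every reference column plus one column
per observed insertion offset, so the consensus can be slightly longer
than any single member genome.  Each column carries a normalized
distribution over the five states A, C, T, G and gap; FASTM resolves the
same distribution per sub-population as joint frequencies (row sum =
abundance, grand total = 1), which makes the pooled FASTV view a plain
column sum of the FASTM rows.

## Pileup

CIGAR strings are walked directly: match/mismatch ops vote for read
bases at reference columns, deletions vote for gap, insertions create
insertion columns `(p, k)` anchored after the 0-based reference position
`p`.  A read whose aligned interval covers both bases flanking an
insertion locus without inserting there implicitly votes "no insertion";
at finalization a gap count is imputed at each insertion column for
every such read, so an insertion column's depth equals its spanning-read
count.  When reads insert different lengths at one locus, the locus gets
as many columns as the longest observed insertion and shorter insertions
pad with gaps.  Counting is strand-pooled, order-independent, and skips
unmapped/secondary/supplementary records and (by default) MAPQ 0.
Insertions before the first reference base have no anchor column and are
ignored.  Base qualities are not consumed.

## Error versus sub-population variation

At a column with depth *n*, a non-consensus state observed *k* times is
tested with the exact one-sided binomial tail P(X ≥ k), X ~ Binomial(n,
e).  The error rate *e* is state-appropriate: substitution_rate/3 for a
base at a reference column (substitution errors are split uniformly over
the three alternatives — no context model), deletion_rate for gap,
insertion_rate for a base at an insertion column.  Error-model presets:
`short` (substitution 10⁻³, indels 10⁻⁵), `long_raw` (0.02/0.04/0.04,
~10 % total, indel-dominant), `long_corrected` (same proportions at 3 %
total).  Long- and short-read chemistries use the same test with
different presets.

Benjamini–Hochberg FDR control is applied jointly across *all*
position×alternative-state tests of the scan, including unobserved
(zero-count) alternatives, which enter the family with p = 1 and emit no
call.  This matters: the tests are selected by having k ≥ 1, and at
realistic depths a single error read already yields p ≈ n·e, so a family
restricted to observed states would declare nearly every singleton
significant.  With the full family, isolated error reads are correctly
absorbed (see the clonal false-positive check) while true minor variants
at the tested frequencies retain essentially all their power.

`min_coverage(f, e, alpha, power)` returns the smallest depth n whose
critical count k*(n) = min{k : P(X ≥ k | n, e) ≤ alpha} is reached by a
frequency-f variant with the requested probability, treating the
observed variant count as Binomial(n, f).  This ignores second-order
error contamination of the variant count — an approximation that is
conservative in the regimes of interest (f ≫ e).  Defaults: alpha 0.05
(FDR level), power 0.95.

## Phasing

Reads are reduced to their observed states at variant sites (sites with
at least one variant-classified state); error-classified observations
become missing.  Clustering is deterministic greedy seed-and-extend:
profiles in decreasing order of covered-site count (ties by read id)
join the first cluster they share ≥ 1 site with at agreement ≥ 1 − tau
(default tau 0.1), else open a new cluster.  A refinement pass then
reassigns each read to its best-agreement cluster until a fixpoint, with
ties keeping the current assignment; this undoes chimeric seeds that the
single greedy pass can lock in.  Clusters sharing at least one site are
merged when their consensus vectors conflict at ≤ tau of the shared
sites — the same tolerance that admits reads, so one error-corrupted
boundary site cannot keep two fragments of one haplotype apart.
Clusters below `m_min` reads (default 5) or local abundance `a_min`
(default 0.01) are dissolved and their reads reassigned or left
unassigned.

A cluster's abundance is its read share among the assigned reads
covering at least one of its sites (reads weighted equally, which is
unbiased under uniform coverage).  Haplotype groups from unlinked
regions are identified as one sub-population by frequency matching:
clusters are sorted by decreasing abundance and chained while
consecutive estimates differ by at most `delta` (default 0.05) plus one
combined binomial standard error of the two estimates — `delta` is the
systematic matching tolerance, the standard-error term absorbs the
sampling noise of estimates backed by finitely many reads.  Within a
chain, clusters sharing a site are necessarily distinct haplotypes and
stay separate; site-disjoint clusters are united.  Mixed chains where
the pairing cannot be resolved by frequency are flagged ambiguous and
kept separate.  Monomorphic linkage components (a single cluster, local
abundance 1) carry no frequency information and are excluded from
matching.  Final abundances are means over matched clusters,
renormalized to 1.

FASTM rows are built from the cleaned counts so that marginalization is
conservative by construction: at each column the pooled mass of every
state is split between sub-populations in proportion to abundance ×
member-read support (at variant columns) or simply by abundance shares
(elsewhere).  Summing rows therefore reproduces the cleaned pooled
distribution exactly; the price is that at variant columns the row sums
track the local read sampling rather than the genome-wide abundance, so
the nominal row-sum-equals-abundance property holds only in expectation
there.  Conservation was chosen as the binding constraint because it is
exact, checkable, and what downstream consumers of the marginal rely
on; validation and parsing treat row-sum drift as a warning by default
with a strict mode available.

## Annotation

Each sub-population consensus (per-column argmax of its renormalized
row; gap-argmax columns dropped, ties broken in canonical state order)
is scanned for ORFs on both strands in all six frames: maximal
start-to-stop genes, bacterial translation table 11, start codons
ATG/GTG/TTG, default minimum length 90 nt.  ORF coordinates are
projected back into gapped-consensus space, and two ORFs share a gene
model iff their projected (start, stop, strand) are identical — the
strictest reading: any coordinate change (moved start, premature stop,
frameshift) issues a new locus group.  Base tags are assigned in
positional order with step 10 (`LT_000010`, `LT_000020`, …); each
(group, sub-population) pair becomes one CDS feature tagged
`<base>_P<k>` with k the sub-population's 1-based rank by abundance, and
a `/frequency` qualifier carrying the abundance.  `/frequency` is a
nonstandard qualifier.  The flat file's ORIGIN is the
insertion-retaining overall consensus.  A gene absent from a
sub-population is simply not emitted (no zero-frequency features).

## Simulator

Sub-population genomes are independent single-step derivatives of one
random ancestor (star phylogeny — a static snapshot; no tree structure,
recombination or time series).  Variants are placed uniformly with
non-overlapping footprints away from the replicon edges (margin 50 bp);
indel sizes are geometric (p = 0.5) capped at 10 bp.  Reads draw their
source genome by abundance; start positions are uniform with overhang
at the replicon edges (overhanging reads are truncated, minimum 30 nt),
so expected coverage is flat across the replicon rather than ramping at
the ends.  Read lengths are fixed 150 nt (short) or lognormal with mean
8 kb (long).  Errors are injected per profile; the true alignment of
every read is composed from the known genome-to-reference edit script
and the injected errors, and written as SAM, so no aligner is needed
downstream.  Quality strings are constant (Q30 short, Q20 long) and not
consumed by the pipeline.  Everything is deterministic under a fixed
seed.

The simulator emulates: mixtures of diverged clones at fixed abundances,
uniform coverage, context-free errors.  It does not emulate real
library/coverage biases (GC, amplification), homopolymer-dependent
indel errors, chimeric reads, paired-end structure, or alignment
artefacts around indels — so green tests demonstrate correctness of the
method under its own model, not performance on real sequencing runs.

## Study conditions used by the tests and the acceptance script

* Two-strain benchmark: 20 kb replicon, abundances 0.7/0.3, 60 SNPs + 3
  small indels, short-read profile at 100× (≈13 300 reads), fixed seeds.
* Error control: clonal 20 kb genomes at 100×, 20 seeds (tests) or 5
  seeds (script).
* Power: 1000–1500 single-column replicates at the computed minimum
  coverage for f = 0.1 under the short-read model.
* Three-strain clustering: 0.5/0.3/0.2 over a 900 bp region carrying 60
  SNPs, so each 150 nt read spans discriminating sites of several
  strains.

These sizes keep a full run in tens of seconds while leaving the
binomial sampling errors an order of magnitude below the tolerances
being checked.

## Numerical choices

* Frequencies are held as fractions in [0, 1]; the 0–100 % scale is a
  serialization option.  Normalization tolerance for in-memory records
  is 1e-6; parsed records are checked at 3·10⁻ᵖ for printed precision p
  (five roundings can shift a unit sum by 2.5·10⁻ᵖ) and never silently
  renormalized.
* Argmax ties break in canonical state order A, C, T, G, gap.
* Uncovered columns are represented explicitly (zero vector, coverage
  0) so coordinates stay dense; the overall consensus renders uncovered
  reference columns as `N` and drops uncovered insertion columns.
* `binomial_tail` delegates to the regularized incomplete beta function
  (exact to machine precision); BH adjustment uses the standard step-up
  with running minima.
* All seeds are explicit; identical inputs give byte-identical outputs
  throughout.

## Limitations

* Genome rearrangements, translocations and large structural changes
  are out of scope by design: the formats cannot represent them.
* Phasing is read-linkage bound: at K > 2 sub-populations, regions where
  read windows contain no discriminating site admit locally consistent
  mosaic (chimeric) clusterings that no deterministic greedy scheme can
  split; probabilistic mixture/EM reconstruction is explicitly a
  non-goal.  Three-way separation therefore requires reads long enough
  to span discriminating sites of multiple strains, as in the dense
  three-strain condition above.  Two-strain separation is robust at
  ordinary SNP densities because every variant site is itself
  discriminating.
* Frequency matching cannot distinguish different sub-populations that
  happen to have the same abundance (flagged ambiguous, kept separate).
* The error model is context-free; homopolymer-aware models,
  strand-bias tests and quality-aware likelihoods are not implemented.
* Reads assignable to multiple clusters at equal agreement stay where
  the deterministic order first placed them; fractional assignment is a
  possible extension.
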