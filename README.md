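# strainspace

Bacterial populations are not clonal: even a culture grown from a single
cell accumulates sub-populations carrying SNPs and small indels, and in
metagenome-assembled genomes these silent sub-populations are flattened
into a single consensus and lost.  `strainspace` is a toolkit for
recording and recovering that within-strain variation.  It implements two
text formats and the pipeline that produces them from aligned reads:

* **FASTV** — a FASTA-like record that stores, for every position of a
  *gapped consensus* (all reference columns plus insertion columns), the
  normalized frequency of the five states **A, C, T, G, gap**, pooled over
  the whole population.
* **FASTM** — the two-dimensional extension: each position carries one
  frequency row per identified sub-population, so sub-populations can be
  tracked individually.  Rows hold joint frequencies — the row of
  sub-population *s* sums to its abundance and the whole matrix of a
  covered column sums to 1, so summing rows recovers the FASTV view.

The pipeline around the formats:

1. **pileup** — per-column state counts from SAM alignments (CIGAR-aware,
   with insertion columns and imputed gaps for reads spanning an
   insertion locus without inserting);
2. **variant statistics** — a one-sided exact binomial test of each
   non-consensus state against the sequencing technology's error rate,
   with Benjamini–Hochberg FDR control across all position×state tests,
   plus a minimum-coverage calculator (smallest depth at which a variant
   at frequency *f* is detectable with given power);
3. **phasing** — greedy linkage clustering of reads over variant sites,
   abundance estimation, and frequency matching of haplotype groups
   across unlinked regions (sub-populations leave the same abundance
   footprint genome-wide);
4. **annotation** — ORF calling on each sub-population consensus and a
   GenBank-like flat file in which conserved gene models share a locus
   tag across sub-populations (`LT_000010_P1`, `LT_000010_P2`, …) while a
   changed model (e.g. premature stop) receives a new tag, each feature
   annotated with its sub-population's frequency;
5. **simulator** — multi-strain mixtures with technology-specific error
   profiles and *true* alignments, so the whole pipeline is testable
   without external data or aligners.

It is aimed at researchers exploring strain-level representations of
high-quality MAGs and at tool developers who need a concrete, testable
reference implementation of per-position variation formats.

## Worked example

Simulate a two-strain mixture (70 % / 30 %, 5 kb, 10 SNPs + 1 indel per
strain, 100× Illumina-like reads), then run the pipeline:

```bash
$ strainspace simulate --config sim.yaml --seed 42 --outdir sim
wrote truth bundle for 2 sub-populations to sim

$ strainspace pileup --sam sim/truth.sam --ref sim/ref.fasta --out counts.tsv
wrote counts for 5000 reference columns and 8 insertion columns to counts.tsv

$ strainspace callvars --counts counts.tsv --error-model short --out calls.tsv
5546 calls, 24 sub-population variants -> calls.tsv

$ strainspace phase --sam sim/truth.sam --ref sim/ref.fasta --out sample.fastm
recovered sub-populations: P1:0.707, P2:0.293 -> sample.fastm

$ strainspace annotate --fastm sample.fastm --out sample.gbk
136 features -> sample.gbk
```

The recovered abundances (0.707 / 0.293) match the simulated 0.7 / 0.3
within the sampling noise of ~3300 reads.  `calls.tsv` separates true
sub-population variants from sequencing errors; at a 1-bp insertion
carried by the minor strain the insertion column `1052+1` (the first
inserted column after reference position 1052) reads:

```
ref_pos  insert_index  state  count  frequency  p_value    q_value    classification
1052     1             A      35     0.3465     1.67e-148  1.68e-144  subpopulation_variant
1052     1             -      66     0.6535     1.0        1.0        consensus
```

and the corresponding FASTM block resolves the same column by
sub-population — the insertion mass sits entirely on `P2`:

```
#1052+1
P1 0.0000 0.0000 0.0000 0.0000 0.6535
P2 0.3465 0.0000 0.0000 0.0000 0.0000
```

Marginalizing the FASTM (`strainspace convert sample.fastm sample.fastv
--to fastv_b`) yields the pooled human-readable FASTV dialect B, which
lists only the states that occur:

```
>ref
1052 A=1.0000
1052+1 A=0.3465 -=0.6535
```

The GenBank-like output keeps one locus tag per conserved gene model with
a sub-population appendix and frequency:

```
     CDS             18..164
                     /locus_tag="LT_000010_P1"
                     /note="subpopulation=P1"
                     /frequency="0.7071"
     CDS             18..164
                     /locus_tag="LT_000010_P2"
                     /note="subpopulation=P2"
                     /frequency="0.2929"
```

The minimum-coverage calculator inverts the binomial test — the smallest
depth at which a variant at frequency *f* is detected with 95 % power at
FDR level 0.05 under the short-read error model:

```bash
$ strainspace mincov --f 0.05 --f 0.1 --f 0.3 --error-model short
f      min_coverage
0.05   59
0.1    29
0.3    9
```

The same functionality is available as a library
(`strainspace.run_pipeline`, `strainspace.simulate_population`, …); see
`docs/methods.md` for the model and parameter choices and
`docs/formats.md` for the exact FASTV/FASTM grammar.

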