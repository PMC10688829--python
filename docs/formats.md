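# FASTV and FASTM format reference

Both formats are line-oriented UTF-8 text in the FASTA family: `>` opens
a record.  Frequencies are printed with a fixed decimal precision
(default 4).  File extensions: `.fastv`, `.fastm`.

## Coordinates

Coordinates are 1-based positions on the *gapped consensus*: every
reference column plus insertion columns.  A reference column is labelled
by its position (`12`); the k-th insertion column after reference
position `p` is labelled `p+k` (`12+2`).  Insertion columns sort between
their anchor position and the next reference position.

## State order

The five states are always ordered **A, C, T, G, -** (gap).

## FASTV dialect A (matrix notation)

```
>record_id optional description
(0.7000,0.3000,0.0000,0.0000,0.0000)
12+1 (0.2500,0.0000,0.0000,0.0000,0.7500)
```

* One line per column: a parenthesized five-tuple in canonical state
  order; all five values are always printed.
* Reference columns are implicit consecutive positions starting at 1 and
  carry no label; insertion columns carry an explicit leading `p+k`
  label.  An explicit integer label on a reference column resets the
  implicit counter.
* An uncovered column is the all-zero tuple.

## FASTV dialect B (human-readable notation)

```
>record_id optional description
1 A=0.7000 C=0.3000
12+1 A=0.2500 -=0.7500
13
```

* One line per column: an explicit position label followed by
  `STATE=freq` tokens for occurring states only; zero-frequency states
  are never printed.
* A label with no tokens is an uncovered column.

## Coverage annotation

With the `with_coverage` serialization option each column line gains a
trailing `cov=<depth>` token recording the observation count.  It is off
by default; parsers accept it in either dialect.

## Percent scale

With the `percent` option values are printed on the 0–100 scale.
Parsers detect the scale from the column sum.

## FASTM

```
>record_id subpops=sp1:0.7000,sp2:0.3000 optional description
#1
sp1 0.7000 0.0000 0.0000 0.0000 0.0000
sp2 0.0000 0.3000 0.0000 0.0000 0.0000
#2+1
sp1 0.0000 0.0000 0.0000 0.0000 0.7000
sp2 0.3000 0.0000 0.0000 0.0000 0.0000
```

* The header declares the sub-population set with abundances that sum
  to 1, ordered by decreasing abundance (ties lexicographic).
* `#<coordinate>` opens a position block; each block contains exactly one
  row per declared sub-population, in declared order: the id followed by
  the five joint frequencies in canonical state order.
* Rows are joint frequencies: the grand total of a covered block is 1,
  and the row of sub-population *s* nominally sums to its abundance.
  Records built from read data relax the row-sum property at variant
  columns, where rows reflect the local read sampling; parsers warn
  about such columns by default and reject them only in strict mode.
* An all-zero block is an uncovered column.

## Tolerances

Printing five values at precision *d* can shift a column sum by up to
2.5·10⁻ᵈ, so parsers accept |sum − 1| ≤ 3·10⁻ᵈ (the precision is
inferred from the printed decimals) and never silently renormalize.
Writers are byte-deterministic: identical records produce identical
files.
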