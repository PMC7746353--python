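# tsrnakit

Analysis toolkit for **tRNA-derived small RNAs** (tsRNAs): classification and
systematic naming of tRF/tiRNA fragments from small-RNA-seq, TPM
quantification and differential calling, miRNA-style consensus target
prediction, hypergeometric pathway enrichment, and tsRNA–mRNA–pathway
network export. It is aimed at transcriptomics researchers profiling tsRNAs
in organisms (such as rat) that lack curated tsRNA databases, and it ships a
synthetic-data generator so every stage can be exercised and validated with
known ground truth.

## The analysis

Mature tRNAs fold into a cloverleaf with three hairpin loops (D, anticodon,
T, 5'→3'). Cleavage position defines six fragment types:

| type | origin |
|---|---|
| tRF-5 | mature 5' end → before the anticodon loop |
| tiRNA-5 | mature 5' end → within/beyond the anticodon loop (5' half) |
| tRF-3 | after the anticodon loop → mature 3' end (carries CCA) |
| tiRNA-3 | within/before the anticodon loop → mature 3' end (3' half) |
| i-tRF | internal, anchored at neither end |
| tRF-1 | U-rich 3' trailer of the precursor transcript |

Each distinct fragment sequence is named
`<organism>-<type code>-<amino acid>-<length><variant>` (e.g.
`rno-tRFi-Ser-25a`), with variant letters assigned by abundance.

Expression is normalised as **tag counts per million of total aligned tRNA
reads (TPM)**; groups are compared with a two-sided pooled-variance
Student's *t* test, calling a fragment differential when
|log₂ FC| > log₂ 1.5 and *P* < 0.05.

Targets are predicted by three independently implemented rule engines and
intersected (consensus):

1. **seed matching** — 7-nt sliding windows; exact 3'UTR matches of the
   reverse complement (7mer) or of positions 2–7 plus an A opposite
   position 1 (7mer-1a);
2. **pairing filter** — perfect Watson–Crick pairing at tsRNA positions
   2–11 and at most 4 mismatches at 12–21;
3. **duplex stability** — nearest-neighbour stacking free energy of the
   best ungapped antiparallel duplex below −20 kcal/mol.

Validated targets (consensus ∩ differentially expressed mRNAs) are tested
for pathway enrichment with the accumulative hypergeometric distribution
(P = Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n)), keeping terms with *P* < 0.01,
observed count ≥ 3 and enrichment factor k/(nK/N) > 1.5, and exported as a
bipartite tsRNA → mRNA → pathway edge list.

## Worked example

Run the whole synthetic study (two groups × 3 replicates, 50k reads per
sample by default; here a lighter run) from the command line:

```bash
tsrnakit all --seed 4 --outdir allrun
```

which logs

```
fragments: 31  venn: 31/31 union 31 ∩ 31  significant: 8  validated targets: 6
outputs → allrun
```

meaning: 31 distinct named fragments were recovered (every planted fragment,
all detected in both groups), the 8 fragments carrying planted 4-fold
changes — and no others — were called differential, and 6 consensus target
genes intersected the significant DE-mRNA table. `allrun/` then contains the
reference panel, fragment table, counts/TPM matrices, composition tables,
differential calls, target calls, enrichment table, network edge list and a
run manifest with content hashes. The same stages are available as
subcommands (`simulate`, `prep`, `classify`, `quantify`, `diff`, `targets`,
`integrate`, `enrich`, `network`) and as library functions
(`tsrnakit.run_pipeline`).

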