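# Methods

## Reference model

tRNA references are stored as 3-line records (header, mature sequence,
dot-bracket structure). Coordinates are 1-based closed intervals on the
mature sequence, matching the convention of the tRNA literature; mature
sequences carry the CCA terminus and are flagged as such, so 3'-anchored
classification treats the final 3 nt as part of the 3' end. Hairpin loops
are located purely structurally: a loop is a maximal unpaired run whose
flanking positions are paired with each other. The 1st loop is the D-loop
and the 2nd the anticodon loop; because long-variable-arm tRNAs (Ser, Leu)
can present a 4th hairpin between the anticodon and T arms, the **last**
loop is taken as the T-loop. `>`/`<` are accepted as bracket aliases to
tolerate tRNAscan-SE-style output. Precursor context is reduced to the 3'
trailer, passed as a header attribute; tRF-1 fragments are taken from this
3' trailer (the convention of the tRF literature, although one source text
describes the trailer as "upstream").

## Read preparation

Reads are 4-line FASTQ; quality strings are carried through untouched and
no quality filtering is applied. The 3' adapter is located by scanning
5'→3' for the earliest window matching the adapter's first 8 nt with at
most `max_adapter_mismatch` substitutions (default 1). A seed hit must then
be confirmed over up to 16 adapter bases with a proportional allowance (1
mismatch per 8 nt); without this confirmation, chance 8-nt look-alikes
inside the insert cause premature trims often enough (≈1% of random
inserts) to violate the ≥99% insert-recovery target at a 1% sequencing
error rate. Windows at the read's 3' end shorter than the seed are matched
over the available overlap (minimum 3 nt) so partial adapter run-in is
trimmed. A 5' adapter, when configured, is removed by the suffix-anchored
analogue. Survivors must satisfy `min_len < length ≤ max_len` with
`min_len = 15` **exclusive** (a 15-nt read is discarded, honouring the
"more than 15 nt" rule) and `max_len = 50`, the library's size-selection
window. No adapter sequences are baked in; they are configuration only.

## Classification and naming

Fragment sequences are aligned to mature tRNAs and trailers exhaustively
(forward strand, substitutions only, default 0 mismatches; small-RNA
libraries are stranded). With mature length L and anticodon loop AC, a
fragment is 5'-anchored when start ≤ 1 (tolerance `tol5`, default 1) and
3'-anchored when end ≥ L − 3 (`tol3` = 3, CCA slack):

* both anchors → full-length molecule, excluded;
* 5' only → tRF-5 if it ends before AC, else tiRNA-5 (the anticodon loop is
  the minimum cut point; no upper bound on the 5' half);
* 3' only → tRF-3 if it starts after AC, else tiRNA-3 (symmetric rule);
* neither → i-tRF;
* trailer hits → tRF-1, required to start within 2 nt of the mature 3'
  boundary to exclude spurious precursor hits.

Fragments are keyed by sequence and counted once regardless of how many
tRNA genes they hit (the TPM denominator is total aligned reads, and a name
carries a single amino-acid family). Family is assigned by majority vote
over hits with an alphabetical tie-break; the same majority rule is applied
to the (rare) case of type disagreement between hits, with a fixed
type-order tie-break. Within each (type, family, length) group variant
letters a, b, c… follow descending total abundance, ties broken by
lexicographic sequence — the naming convention does not specify an order,
and determinism is required; more than 26 variants is an error rather than
an ambiguous name.

## Quantification and differential calling

TPM is counts divided by the sample's total aligned tRNA reads × 10⁶ — a
normalisation within tRNA space, so each sample's column sums to 10⁶.
Composition tables (per type, amino acid, length) are TPM-weighted within
each group. Detection for Venn/profile membership is a nonzero raw count in
at least one replicate of the group. The differential test is a two-sided
unpaired pooled-variance Student's *t* on TPM (not log-TPM), taken
literally; when both groups are constant and equal, P = 1 by convention.
Fold change uses group means with a pseudocount ε = 0.01 TPM (roughly the
smallest meaningful TPM at realistic depth) applied to the ratio only,
never to the test; log₂FC is computed as a difference of logs so that
swapping group labels negates it exactly. Significance requires
|log₂FC| > log₂ 1.5 and P < 0.05 with no multiple-testing correction,
mirroring the profiling convention this pipeline reproduces. No expression
floor beyond the detection rule is applied.

## Target prediction

Positions on the tsRNA are numbered 5'→3' from 1, miRNA-style; a UTR site
opposes them antiparallel. The three engines are deliberately independent:

* **Seed engine.** Every 7-nt window (L−6 windows) is searched as an exact
  reverse-complement match in the UTR (7mer) or as positions 2–7 reverse
  complement followed by an A opposite position 1 (7mer-1a). Sites are
  deduplicated by (window offset, UTR position); 7mer evidence outranks
  7mer-1a at the same site.
* **Pairing engine.** Anchored at the seed-match register: perfect
  Watson–Crick pairing at positions 2–11 and ≤4 non-complementary opposing
  bases at 12–21. G:U wobble counts as a mismatch here ("perfect pairing"
  is read strictly). For tsRNAs shorter than 21 nt the tail span is
  truncated and the allowance prorated as ⌊4 × span/10⌋ — a defined
  truncation instead of undefined behaviour. Sites matched so close to the
  UTR 3' end that the tsRNA 5' region has nothing to oppose fail rule (i).
* **Energy engine.** A nearest-neighbour stacking model over the best
  ungapped antiparallel registration: initiation +4.09 kcal/mol, published
  Watson–Crick RNA stack free energies (37 °C) embedded as data, a flat
  −0.5 kcal/mol for any stack involving a G:U wobble (weakly stabilising),
  and +1.0 kcal/mol per opposed-but-unpaired position. Ungapped
  registration keeps the model deterministic and checkable against plain
  summation; it is a simplification relative to full hybridisation dynamic
  programming (no bulges or asymmetric loops). Threshold: MFE < −20
  kcal/mol.

A site is consensus iff all three engines pass; a gene is a consensus
target when it carries ≥1 consensus site.

## Integration, enrichment, network

Validated targets are the per-tsRNA intersection of consensus genes with
significant DE mRNAs (same |log₂FC| > log₂ 1.5, P < 0.05 flag). Enrichment
uses the accumulative (upper-tail) hypergeometric distribution with
universe = all genes in the annotation file (config-overridable; the
original web tool's internal universe is not recoverable). Gates: P < 0.01,
observed ≥ 3, enrichment factor > 1.5, applied to raw P; a
Benjamini–Hochberg column is emitted for information only. Term clustering
by membership similarity is out of scope — the term list is flat. The
network is bipartite-by-kind (tsRNA→mRNA `targets`, mRNA→term `member_of`),
deduplicated, with terms restricted to those passing the gates when any do.

## Synthetic data generator

The generator emulates a two-group (sham vs ICH) rat brain small-RNA study
and is the source of every pipeline input in the tests:

* **References** — 76-nt canonical cloverleaf scaffold (fixed pairing;
  loops at 14–21, 32–38, 54–60; anticodon at 34–36), randomised
  stem-compatible bases, CCA-appended, one anticodon per amino-acid family,
  2 isodecoders × 10 families by default. Trailers are 16–20 nt with U
  fraction ≥ 0.5 by construction; the lower bound is 16 (not 12) so a
  whole-trailer tRF-1 survives the >15 nt read filter.
* **Reads** — fragment endpoints drawn conditional on type (e.g. tiRNA-5:
  start 1, end uniform in the anticodon loop; tiRNA-3 start down to 28 to
  populate the 49-nt band), with the type mixture calibrated to reported
  brain composition (tiRNA-5 0.3836, tRF-3 0.2129, tRF-1 0.0012; the text
  gives no split for the remaining three types, so the rest of the mass is
  divided evenly, config-exposed). Lengths fall in the 16–23 / 29–36 / 49 nt
  bands. Replicate counts are negative-binomial with mean per group and
  CV 0.1 (r = 1/CV²) — overdispersion is the norm for RNA-seq counts.
  Planted log₂ fold changes (default 8 fragments at ±2) go to the
  *smallest* mature fragments above a 0.2% abundance floor: TPM is
  compositional, and planting effects on dominant fragments would shift
  every null fragment's TPM by the group mass ratio, contaminating the
  null. Reads are emitted as insert + full 3' adapter (variable read
  length; no fixed cycle count is simulated), shuffled deterministically.
  Substitution sequencing errors are available (`seq_error_rate`, default
  0 for byte-reproducible pipelines).
* **Targets** — random UTRs of 200–2000 nt; planted consensus sites are
  exact antiparallel complements of a tsRNA's first 21 nt (an AU-rich
  tsRNA whose perfect duplex cannot clear −20 kcal/mol is skipped for
  another, bounded retries); decoy sites satisfy only an interior seed
  match. The DE table marks 20 genes significant, 6 of which are planted
  target genes, mirroring the predicted/DE/validated intersection structure
  of the study at desk scale; the annotation groups genes into terms of
  sizes (15, 12, 10, 8, 5) with the validated overlap planted into the
  first term.

One RNG stream per artifact (references / reads / targets) is derived from
the master seed, so perturbing one stage never reshuffles another.

What the generator does **not** emulate: sequencing quality profiles, PCR
duplicates, tRNA-modification read-through artifacts, indels,
mitochondrial-vs-nuclear ambiguity, or real GtRNAdb sequence diversity.
Passing tests therefore demonstrate correctness of the rules and statistics
under clean, planted-truth conditions, not performance on real libraries.

## Problem sizes and numerics

Default tests run at 5k–20k reads per sample; composition recovery is
checked at 200k reads per sample on the count path (the FASTQ round trip is
exercised end-to-end at the smaller depths). Oracle suites compare against
brute-force enumeration: all (start, end) pairs on a 76-nt tRNA, exhaustive
seed scans on 500 random pairs, plain nearest-neighbour summation (1e−9),
exact combinatorial hypergeometric tails for universes ≤ 60 (1e−12), and
the textbook pooled-variance *t* formula (1e−9). All outputs are written
atomically (temp file + rename) and a manifest records config and output
hashes; reruns at a fixed seed are byte-identical.

## Known limitations

* The energy model is a stand-in for full RNA–RNA hybridisation: ungapped,
  flat wobble/mismatch penalties, no dangling ends or loop entropy.
* The seed engine represents the "perfect match" class of predictors; the
  original external tools' proprietary scores (context scores, alignment
  scores) are intentionally out of scope.
* t-tests on TPM with n = 3 and no multiple-testing correction reproduce
  the source convention; they are not a recommendation for new study
  designs.
* Alignment is substitution-only and forward-strand; heavily modified or
  edited fragments would be undercounted on real data.
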