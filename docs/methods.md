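# Methods

This note records the models, parameter choices and numerical
conventions behind `hdrscreen`, and what the synthetic-data validation
does and does not establish.

## Screen generative model

`synthetic_data.simulate_screen_counts` draws one screen from the
following model. Each guide g carries an HDR probability

    p_g = clamp( base_hdr * m(gene) * 2^eps_g , 0, 1 ),   eps_g ~ N(0, sigma)

where `m(gene)` is the programmed effect multiplier (default 1) and
`sigma = guide_noise_sd` (default 0.25 on the log2 scale) models
guide-to-guide knockdown efficacy. Efficacy can only express itself
through an effect: a guide whose gene has `m = 1` changes nothing
whether or not its knockdown works, so `eps` is applied only to guides
of genes with `m != 1`. Non-targeting controls sit exactly at
`base_hdr`. This is deliberate and load-bearing: it makes true-null
genes exchangeable with the control guides, which is the assumption
underlying the control-based Mann–Whitney null. Giving null genes extra
log-normal spread that controls lack would make the test
anti-conservative by construction (measured ~8% of null genes below
p = 0.05) — a property of that mis-specified generator, not of the
statistics.

Cells (default 500 per guide) are distributed over guides by a single
multinomial; each guide's HDR cells are Binomial(cells_g, p_g). Sorting
is imperfect: HDR cells enter the GFP+ bin with probability
`sorting_purity` (default 0.98; FACS gates are never pure, and the
value is a generator choice — no purity is observable from count data
alone), and non-HDR cells contaminate it at `1 − purity`; the NON bin
is the complement. Sequencing of each population (PRESORT, GFP, NON) is
one multinomial over that population's cell composition with total
depth `reads_per_guide_depth × n_guides` (default 500 reads/guide), so
column sums are exact by construction.

Defaults (`ScreenSimParams`): 2000 genes × 5 guides + 250 controls
(tests of the null use 500 controls so the control distribution is well
resolved), `base_hdr = 0.05`, depth 500. These are the study conditions
of the screen design the package targets, scaled only in the number of
cells.

What the generator does **not** emulate: PCR jackpotting and chimeras,
guide dropout during library culture, knockdown-efficacy correlation
across guides of one gene, fitness effects of knockdown, and
sequencing-error cross-talk between guides (cassette reads are emitted
error-free, matching the exact-match counting policy). Passing tests
therefore show the statistics are correct under a faithful sorting
model, not that they are robust to every real-library artifact.

## Screen statistics

* **Counting** is exact forward-orientation protospacer matching; a read
  containing the protospacers of two different guides is unassigned.
  Nested protospacers are rejected at library load. Mismatch-tolerant
  recovery is out of scope.
* **Normalization** is counts-per-million over assigned reads. The
  alternative (median-of-controls scaling) changes nothing downstream
  because enrichment is a ratio of the same two samples; CPM is the
  tested default for its simplicity and scale invariance.
* **Guide enrichment** uses a pseudocount of 1.0 on the CPM scale, which
  keeps every log2 ratio finite and shrinks low-count noise; guides with
  baseline CPM < 1 fail QC and are excluded from gene statistics.
* **Replicates** are processed independently and guide enrichments
  averaged before gene-level statistics; a guide must pass QC in every
  replicate.
* **Gene collapse** is the mean of the k = 3 guides with the largest
  absolute enrichment (signed values averaged). Under a five-guide
  design with variable efficacy, the most extreme guides carry the
  signal; the rule is isolated in `collapse_gene_score` so an alternate
  collapse is a one-function swap. Genes with fewer than k guides are
  flagged; fewer than 2 usable guides yields p = NaN and never a hit.
* **Significance** compares each gene's guide enrichments to the pooled
  control-guide distribution, two-sided. Exact U enumeration is used
  when n ≤ 8 guides and m ≤ 12 comparison values are tie-free;
  otherwise the tie-corrected normal approximation with continuity
  correction. In a real screen the control set is large, so the
  asymptotic path is the operative one; the exact path exists for small
  designs and is verified against full rank-configuration enumeration.
* **Hit calling** uses raw p < 0.005, strictly (p = 0.005 is not a
  hit). No multiple-testing correction is applied, matching the
  volcano-plot convention this threshold comes from; a
  Benjamini–Hochberg column is emitted for information only.
* **Unity normalization** covers only genes with score < 0 ("essential"
  for the repair outcome): Z = (score − min)/(max − min) over that
  subset, binned by half-open intervals [0,0.2), [0.2,0.4), [0.4,0.6),
  [0.6,0.8), [0.8,1]. A caller-supplied override set carries designated
  positive-score genes into bin 5 with undefined Z; other positive
  scores get no comparison record. The override is an input, not a
  hard-coded gene list.

Analytic expectations used by the recovery checks
(`expected_guide_enrichment`, `expected_collapsed_score`) evaluate the
model at the guide-noise median and add the extreme-guide selection
shift `sigma * E[mean of top-k of n standard normal order statistics]`
(computed by quadrature). The approximation assumes the effect is well
above the guide noise, which holds at multiplier 4.

## Amplicon editing pipeline

* **Adapter trimming** removes the longest read suffix matching a prefix
  of the adapter (minimum 3 nt, one mismatch allowed per 10 nt).
* **Merging** reverse-complements mate 2 and consumes the overlap
  maximizing matching bases (≥ 10 nt, mismatch fraction ≤ 0.2; ties go
  to the longer overlap). Disagreements resolve to the higher-quality
  base, ties to mate 1. Failures are counted and excluded from the
  aligned-read denominator.
* **Alignment** is global Needleman–Wunsch with affine gaps in the
  three-state (Gotoh) formulation; a gap of length L costs
  `gap_open + gap_extend·(L−1)`, end gaps are penalized, and N scores
  as a mismatch against everything. Defaults (+5/−4/−10/−0.5) follow
  the classic EDNAFULL global-alignment convention; all four are
  CLI-exposed. Traceback is deterministic: on ties, diagonal, then gap
  in the reference, then gap in the query. The within-row gap
  recurrence is solved by a running maximum in closed form; with the
  default half-integer scoring grid all arithmetic is exact in floats,
  so the closed form and the literal recurrence coincide bit-for-bit.
* **Cut placement**: the blunt SpCas9 cut sits between protospacer
  positions 17 and 18 (3 nt 5' of the NGG PAM), strand-symmetric,
  inferred when the spec omits `cut_index`. Coordinates are 0-based;
  the cut falls between `cut_index − 1` and `cut_index`.
* **Indel window**: "a six base pair window around the cut" is read as
  half-width 3 (three bases each side of the blunt cut); the total-width
  ±6 reading is genuinely possible, so `window_halfwidth` is a spec/CLI
  parameter and the test suite exercises both. An insertion is
  in-window when its insertion point lies in [cut−w, cut+w]; a deletion
  when its span overlaps [cut−w, cut+w).
* **Template choice**: the read is aligned to both reference and donor;
  the higher score wins, ties go to the reference (conservative —
  biases against over-calling HDR). Reads below 50% of the reference
  length, or scoring below 60% of the chosen template's maximum
  attainable score, are AMBIGUOUS (the floor is arbitrary but logged;
  it keeps garbage reads out of the unedited count).
* **Flag reading**: per-flag conversion is the read base aligned at the
  flag position *of the chosen template's alignment* (donor coordinates
  when the donor wins). Reading flags from the reference alignment is
  equivalent for indel-free reads but ambiguous when a window indel
  abuts a flag, where tie-broken gap placement can absorb the flag
  column.
* **Categories**: all flags converted + no window indel → HDR; window
  indel without full conversion → NHEJ; both → MIXED; neither → 
  UNEDITED. Reads with some-but-not-all flags converted and no window
  indel fit none of these definitions and are reported AMBIGUOUS
  (partial conversion); their information is retained by the per-flag
  frequencies. For donors that are a pure insertion cassette with no
  SNP flags, conversion is carried by the cassette itself (the donor
  template winning the alignment).
* **Rates**: denominators are aligned reads = total − merge failures −
  AMBIGUOUS. The HDR rate is #HDR/aligned. The NHEJ rate counts *every*
  read with a window indel, i.e. (#NHEJ + #MIXED)/aligned — donor
  conversion does not excuse an indel at the cut — and the MIXED
  fraction is also reported separately so either accounting can be
  reconstructed. The four category fractions partition aligned reads
  exactly; the ambiguous fraction is reported over total reads. With
  zero aligned reads, rates are NaN, never 0.

### Amplicon read generator

Templates are whole-amplicon sequences: reference, donor, centered
deletions `delN@pos`, insertions `insN@pos` (random bases, drawn once
per template), and partial-conversion templates. One seeded multinomial
assigns templates to the `n_reads` reads (default 10,000, the depth
floor of the assay emulated); per-base substitution errors (default
10⁻³) are applied to the fragment, which is then split into overlapping
mates with adapter read-through when the fragment is shorter than the
read length. Sequencer indels are not simulated by default so that
indel-based classification truth stays unambiguous; errors are shared
between mates (applied at the fragment level, like a PCR error).
Quality scores are constant, so quality-aware merge resolution is
exercised only by constructed unit-test reads.

The canonical fixture (`example_amplicon_spec`) is a synthetic 72-nt
amplicon — protospacer at offset 25, TGG PAM, cut at 42 — with two
donor SNP flags: one inside the protospacer and one destroying the PAM
(the standard recut-blocking donor design).

## Determinism and problem sizes

Every generator takes one seed and fans it out to per-component child
seeds through `numpy.random.SeedSequence`; identical parameters and
seed give byte-identical FASTQ output. The test suite and acceptance
script run the screen checks at 2000 genes × 5 guides + 500 controls,
depth 500, ten seeds pooled for the null (20,000 gene-level tests), and
the amplicon recovery at 10,000 reads; aligner and U-test oracles use
exhaustive enumeration at lengths ≤ 6 and sample sizes n ≤ 6, m ≤ 8.
These sizes resolve the quantities being checked (binomial SE ≈ 0.005
on a rate at n = 10,000; ±0.003 on a 5% null fraction at 20,000 genes)
while keeping a full run around a minute on one CPU.

## Known limitations

* Exact-match guide counting undercounts libraries sequenced at high
  error rates; no UMI or staggered-primer handling.
* The classifier targets substitution donors and short indels; large
  cassette knock-ins are only minimally supported (no per-junction
  analysis), and quality-aware likelihood classification is out of
  scope.
* The GFP-vs-PRESORT contrast is the tested default; the NON bin is
  simulated and counted but which contrast a given screen should use is
  an analysis choice exposed to the caller.
* p-values are raw by design (strict p < 0.005 hit threshold); users
  wanting FDR control should use the emitted BH column.
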