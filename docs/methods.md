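# Methods

This note documents the models, numerical choices and known limitations
behind `scsomatic`, in the order data flows through the package.

## Allele pileup and molecule consensus

Evidence is counted per molecule, not per read: reads sharing a
`(cell barcode, UMI)` pair are PCR copies of one cDNA molecule. The
pipeline is

1. **Read filters.** A read must carry both `CB` and `UB` tags and have
   base quality ≥ 1 *and* mapping quality ≥ 1 at the site (quality-0
   evidence is discarded; the thresholds are inclusive and configurable).
   When a filtered barcode list is supplied, the read's barcode must be on
   it; `-1`-style GEM-group suffixes can be normalized at load so lists of
   either dialect compare equal. Mate pairs are deduplicated by query name
   (keeping the higher-base-quality mate) so one fragment never counts a
   molecule twice.
2. **Consensus.** If duplicate reads disagree at the variant base, the
   modal base is accepted when its frequency is ≥ 0.75 (inclusive — 3 of 4
   reads suffice, 3 of 5 do not); otherwise the whole molecule is
   discarded and flagged discordant. Consensus is permutation-invariant in
   read order.
3. **Classification.** The consensus base is classified against the site:
   `ref`, `alt`, or `other`. Third alleles are never counted as mutant
   *or* wild-type — they contribute to coverage and to scVAF denominators
   only. This prevents a recurrent sequencing artifact from inflating
   either side.

**Coordinates.** VCF input is 1-based; conversion to 0-based happens
exactly once at parse time (`VariantSite.pos0`). Allele pairs are
string-trimmed (shared prefix/suffix) at parse time; reference-aware
left-shifting across repeat copies is out of scope and multi-allelic
records must be split upstream.

**Indels.** A read supports the alternate allele when its cigar contains
an insertion/deletion operation of the expected type and length whose
reference placement falls within ± `window` (default 10 bp) of the
position immediately after the anchor base. Droplet reads over short
repeats are frequently misaligned by a few bases, which is what the window
absorbs; 10 bp is a package choice — wide enough for the repeat units that
cause the problem, narrow enough not to capture unrelated events. A read
supports `ref` only if it spans the full variant interval with no indel
operations at all; a read whose indel falls outside the window is treated
as uninformative rather than as reference evidence. An indel of the wrong
length inside the window is classified `other`.

**Input access.** Indexed BAMs are random-accessed per site; un-indexed
input (e.g. the simulator's plain SAM) is handled in a single streaming
pass. Both paths produce identical calls.

## Genotyping under allelic dropout

For a heterozygous site, each sampled molecule carries the mutant allele
with probability ~0.5, and most sites are covered by at most one molecule
per cell. Absence of mutant evidence therefore never implies a wild-type
genotype. Statuses are:

* `mutant` — at least one consensus mutant molecule (`alt_umis ≥ 1`);
* `ref_only` — coverage (including `other` molecules) but no mutant
  evidence: genotype *unknown*, not wild-type;
* `no_coverage` — no counted molecules.

Per-variant metrics:

* **scVAF** = alt units / (ref + alt + other units). The default unit is
  the UMI-consensus molecule; a `raw_reads` option counts reads instead.
  The molecule unit is the default because PCR duplicates would otherwise
  be double-counted.
* **MCF** = M/T with T the number of cells with coverage at the site.
* **MCDR** = M / (2 · VAF_DNA · T): a heterozygous variant at bulk-DNA VAF
  v should be present in 2v of the cells, so 2·v·T covered cells are
  expected to carry it. The denominator uses T (covered cells), not all
  cells — detection is only possible where there is coverage. MCDR is
  reported uncapped; sampling noise or allele-specific expression can push
  it above 1.

Multi-mutation tallies report, per k ≥ 1, the number and percentage of
mutant cells with exactly k distinct detected mutations; percentages are
rounded to two significant figures, the convention used in published
summary tables. Clone assignment gives each mutant cell the set of
clone-tree nodes whose mutations it expresses; the set is *consistent*
when it lies on a single root-to-leaf path (founding + nested subclone)
and flagged when it mixes sibling branches. Control-sample false-positive
rates are alt units / total units per site over samples known to lack the
variants.

## Detection model

The expected number of detected mutant cells from *n* sequenced cells is

    E = n · a · ( f · [1 − (1 − c·t)^r] + (1 − f) · e )
      ≈ n · a · f · r · c · t + n · a · (1 − f) · e

Symbols and units: *a* tumor-cell fraction; *f* twice the bulk-DNA VAF
(the carrier fraction among tumor cells); *t* relative expression of the
gene as a fraction — the interface accepts CPM and divides by 10⁶, making
*t* the probability that one UMI comes from the gene; *r* average UMIs per
cell; *c* fraction of the gene's molecules covering the variant position;
*e* site-specific false-positive rate. The bracket is the chance that at
least one of a cell's gene molecules covers the site; the right-hand
approximation (first order in c·t) is an upper bound for r ≥ 1 and equals
the exact form at r = 1 or c·t = 0.

Numerical and interpretive choices:

* The inner power is evaluated as `expm1(r·log1p(−c·t))` so the model is
  stable at the small c·t values (10⁻⁶–10⁻⁴) typical of real designs.
* E is an expected count and can exceed 1; `prob_at_least_one` exposes the
  corresponding probability `1 − (1 − q)^n` with q the per-cell term.
* The formula applies *f* multiplicatively with no explicit ½ for
  heterozygous allele sampling inside the bracket. The model is
  implemented exactly as written; where the simulator (which does sample
  alleles) is compared against it, the coverage probability is thinned by
  the allele-sampling probability (c → c·0.5 for heterozygous truth) —
  see "Simulator" below.
* The closed form treats *r* as a fixed per-cell molecule count; the
  Monte-Carlo validator draws per-cell counts from Poisson(r). The
  difference between `1 − (1 − ct)^r` and its Poisson mixture
  `1 − exp(−r·ct)` is second-order in c·t and negligible at the parameter
  scales of interest; the validator is a genuine simulation of the
  generative story, not a re-evaluation of the formula.
* The design inverse returns the smallest integer n with E ≥ target
  (exact, since E is linear in n) and signals infeasibility when the
  per-cell term is 0.

## Coverage profiling

Distances are measured in **spliced transcript coordinates**: exons are
concatenated in transcript orientation (strand-aware), and intronic or
intergenic positions are ignored — a junction-spanning read contributes to
both flanking exonic positions and to nothing in between. Genomic vs
spliced anchoring is a genuine design choice; spliced coordinates are used
because positions off the annotated isoform carry no information about
transcript-relative capture distance.

Per transcript, the unit is the unique `(CB, UB)` pair: a pair "covers" a
position if any of its reads aligns across it, so multi-read molecules
extend coverage (molecule-level framing). Each position's value is
covering pairs / total pairs on the transcript; fractions are computed per
transcript *before* averaging, never pooled. Aggregation anchors at the
TSS (5' kits) or TTS (3' kits), averages at each distance over only the
transcripts long enough to have data there, and truncates at 10,000 bp to
avoid edge effects from the length cutoff. Gene selection keeps genes with
exactly one annotated isoform and spliced length in [250, 11,000] bp,
which avoids ambiguity from alternative start/stop sites.

## Integration statistics

* **QC/normalization.** Cells with fewer than 10 expressed genes, > 50%
  ribosomal (RPS/RPL prefixes) or > 10% mitochondrial (MT- prefix) counts
  are removed; genes expressed in fewer than 3 cells are removed; counts
  are scaled to 10,000 per cell and transformed `log(1 + x)`. The
  pseudocount of 1 is the standard convention. The transform is
  implemented directly (it is three lines); a test cross-checks it against
  scanpy's `normalize_total` + `log1p`.
* **Lineage inference.** Nearest reference profile by Spearman correlation
  (distance 1 − ρ) over shared genes (≥ 10 required); invariant to
  monotone per-cell transforms; ties broken by reference row order;
  constant profiles are an error (rank correlation undefined).
* **Cluster enrichment.** Per cluster, a one-sided Fisher exact test on
  (in/out of cluster) × (mutant / not-detected-mutant). `ref_only` and
  `no_coverage` cells are pooled as "not detected mutant" — under dropout
  they are a mixture of mutant and wild-type cells and cannot be split.
  P-values are reported uncorrected with a p ≤ 0.05 flag by default (the
  convention for this screen); BH correction is available as an option.
  The depleted direction finds normal clusters in mostly-tumor samples.
* **Mutant-density regression.** For each gene i, OLS of cluster-mean
  normalized expression on the cluster's mutant-cell fraction m, with the
  mutated gene's own mean expression g as an optional covariate:
  `E_i = x_i + y_i·m + z_i·g`. Smoothing over clusters sidesteps the
  unknown-genotype problem: rather than contrasting mutant with "not
  mutant" cells, the method asks which genes track the local density of
  confirmed mutant cells. Significance of y is the partial F-test of the
  nested model without m (equivalent to the squared t-test in OLS),
  BH-corrected across genes; selection requires q ≤ 0.05 *and* y > 0
  (positive association), applied after two-sided testing. Cluster means
  are computed on log-normalized values, matching the preceding pipeline.
  Zero-residual fits (perfect fit or constant gene) produce a NaN F
  statistic; they are resolved by the slope (p = 0 if y ≠ 0, else 1).
  A design where m is collinear with g is flagged, not silently dropped.
  The subclone-level variant of the analysis omits g.
* **Wilcoxon signature.** Cells are pooled by whether their cluster's
  mutation fraction exceeds 0.10 — strictly, so a cluster at exactly 10%
  is non-rich — and each gene is tested rich vs rest with the two-sided
  rank-sum test (average ranks, normal approximation with continuity
  correction), BH-corrected.
* **Correlation screen / overlap.** Pearson r of every gene against an
  anchor gene across bulk samples (≥ 10), p from the exact t transform,
  BH q, inclusion at q < 0.001 regardless of sign; the anchor itself is
  excluded. Gene-set overlap significance is the upper-tail hypergeometric
  probability of at least the observed intersection; the gene universe is
  an explicit required argument because the result is meaningless without
  stating it.

## Simulator

The generator emulates the generative assumptions of the detection model
with known ground truth, so every pipeline stage can be scored exactly.

Per simulation: cells are tumor with probability `tumor_fraction`; tumor
cells are assigned to a clone tree by nested fractions (children of a node
partition a fraction of its cells; fractions summing above 1 are
rejected) and carry the variants on their root-to-node path. Per cell and
gene, the molecule count is Poisson(r · CPM/10⁶); in a carrier each
molecule is mutant with probability `het_prob` (0.5 — heterozygous
sampling; 1.0 gives homozygous mode); each molecule covers the variant
with probability `site_coverage`; each molecule emits one read plus one
duplicate with probability `duplicate_fraction`; each covering read's site
base is replaced by a uniformly random different base with probability
`error_rate`. Optional knobs inject forced duplicate discordance,
quality-0 reads, and untagged reads for filter testing. Reads are
single-end, fixed-length, with exact-match cigars except at indel sites
(I/D operations of the planted length); each gene is its own contig and a
matching FASTA reference is written so headers are self-consistent.

Default conditions mirror a droplet 5' AML bone-marrow run: 17,965 cells
(a typical per-sample recovery), 50% tumor, 2,000 UMIs/cell, 2.5% site
coverage (the distal-coverage level of 5' libraries), per-read error
10⁻³, duplicate fraction 0.1, and a clone tree of a founding clone
(DNMT3A SNV + NPM1 4 bp insertion, the classic AML founding lesions) with
a 30% nested subclone (GATA2 SNV). Tests and the acceptance script run
the same generator at 600–3,000 cells, which keeps the full suite fast
while leaving per-variant molecule counts in the hundreds-to-thousands
range where the statistical checks are well powered.

Consequences of the design, and what it does not model:

* With `error_rate = 0` and no duplicates, the emitted-molecule truth
  table is reproduced *exactly* by the pileup: genotype precision is 1.0
  by construction, and any mismatch is a bug, not noise.
* The per-site false-positive rate implied by the read model is
  `error_rate / 3` for SNVs (errors are uniform over the three other
  bases) and 0 for indels (substitution errors cannot fake a cigar
  indel); the truth table records these per site.
* Expression matrices are generated separately: clusters with specified
  mutant fractions m, signature genes whose cluster-mean log expression
  rises as `baseline + effect_size · m`, log-normal cell-level noise
  (sd 0.2) around cluster means, Poisson counts at a 10,000-molecule
  target depth. With 100 cells per cluster the noise on cluster means is
  ~0.02 log units, so the default planted effect (1.5 over an m range of
  ~0.6) is comfortably detectable; this matches the regime in which the
  density regression is meant to operate (many cells, few clusters).
* Not modeled: full transcript sequences, splicing, positional error
  profiles, barcode collisions/correction, ambient RNA, allele-specific
  or bursty expression, large structural events (ITDs, fusions). Passing
  tests therefore demonstrate correctness of the counting, consensus and
  statistical machinery under the stated generative assumptions — not
  robustness to alignment artifacts or library pathologies of real data.

## Degenerate inputs and tie-breaks

Zero UMI groups make the discordance rate undefined (error, not 0); zero
counted units make scVAF undefined; T = 0 makes MCF/MCDR undefined; a
missing or zero bulk VAF makes MCDR undefined; an empty post-QC matrix,
a constant anchor gene, a constant m, and an empty Wilcoxon group are all
explicit errors naming the cause. Consensus ties below 75% discard the
molecule; Spearman lineage ties break by reference order; the consensus
threshold and the mutant-rich threshold are inclusive (≥ 0.75) and strict
(> 0.10) respectively, matching their definitions.

## Limitations

Cell-based sensitivity is intrinsically low: most sites are covered by a
single molecule per cell, so even perfect chemistry detects a clonal
heterozygous variant in roughly half of the covered carrier cells (MCDR
≈ 0.5 at single-molecule coverage), and "wild-type" can never be
concluded for an individual cell. The detection model treats molecule
coverage as independent across molecules and ignores allele-specific
expression. Genotype matrices from this approach are generally too sparse
for de novo subclonal reconstruction; clone structure is consumed as
input, not inferred.
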