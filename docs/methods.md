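# Methods

This note documents the models, conventions and parameter choices behind
`rg4rgg`, the assumptions each one carries, and what the synthetic-data
tests do and do not demonstrate about real transcriptomes.

## Coordinate conventions

All intervals are 0-based, half-open, in *transcript space*: position 0 is
the first nucleotide of the 5′ UTR flank, so a motif spanning protein
residues `[s, e)` occupies nucleotides `[f5 + 3s, f5 + 3e)` where `f5` is
the 5′ flank length (≤ 50 nt). The internal nucleotide alphabet is DNA;
`U` is normalized to `T` on input and reported back as `U` only in
nucleobase-composition tables. Experimental regions may extend beyond the
CDS; they count wherever they intersect a motif coding interval.

## The RGG motif grammar

A motif is `RG{1,2} (X{0,4} RG{1,2})+`: at least two RG or RGG repeat
units, interspersed by linkers of up to four arbitrary residues. The
analytic minimum length is 4 (`RGRG`), verified by exhaustive enumeration.
Matching is *maximal leftmost-longest* with greedy unit absorption:

* a lazy linker always absorbs the nearest next unit. This never shortens
  the reachable extent, because any unit skipped by a longer linker would
  itself be reachable from the absorbed one (units cannot overlap, and a
  skipped unit starts within linker range of the previous unit's end);
* extension is always preferred over terminating a match, and matches are
  emitted left to right without overlap;
* a motif starts at the R of its first unit and ends at the final G of its
  last unit: trailing would-be linker residues (e.g. the third G of
  `RGGRGGG`) are outside the span;
* motifs never span the unknown residue `X` or a stop placeholder `*`.

The detector is regression-tested against an independent brute-force
oracle (recursive grammar membership plus exhaustive leftmost-longest
selection) on random strings. Where a convention was open — e.g. whether
`RGGG` parses as `RGG`+linker-G — the greedy reading above was adopted and
is pinned by tests.

## rG4 assignment

**G4Hunter-style scoring.** Each base scores by its run: a G in a maximal
G-run of length k scores `min(k, 4)`, a C the negative, others 0. Windows
(default 25 nt, the original tool's convention) with mean ≥ threshold
(default 1.2) are merged and the merged span trimmed to start and end on a
G. Only the positive strand is reported: rG4s fold on the given mRNA
strand. A sequence shorter than the window is one window. Raising the
threshold provably shrinks the covered nucleotide set (tested).

**QGRS-style scanning.** Candidates are four G-tracts of ≥ 2 consecutive
guanines separated by three loops of length ≥ 0 (at most one zero-length
loop), total length ≤ 30 nt. The G-score used is

```
score = 13·(tract length) − mean(loops) − mean(|loop − mean(loops)|)
```

a transparent formula satisfying the three defining axioms of
quadruplex-forming potential — more stacked tetrads score higher
(dominant), shorter loops score higher, and for a fixed total loop length
the most even split scores highest — on the conventional threshold scale
(default 19: a two-tetrad candidate passes with short loops and fails with
long uneven ones). Overlaps are resolved greedily by descending score,
ties to the leftmost then shortest candidate. Candidate enumeration is
tested against an independent brute-force window enumerator; the score is
tested against its axioms by exhaustive loop enumeration.

**Experimental routes.** BED interval calls are validated (line-numbered
errors) and merged per transcript. RT-stop positions expand to
`[max(0, p − 60), p)` — the 60 nucleotides upstream of the stalled reverse
transcriptase, stop nucleotide excluded — and merge. Multi-sample consensus
keeps maximal runs of positions supported by ≥ 2 samples (nucleotide-level
counting, each sample counted once per position).

## The overlap criterion

A motif is *partly encoded* by an rG4 when one merged region overlaps its
coding interval by at least 6 consecutive nucleotides (`max_single_overlap
≥ cutoff`). Regions from one source are merged first with adjacency
counting as contiguity, so two abutting calls form one consecutive
stretch. Union statistics (`overlap_nt`, `coverage`) are computed over all
regions. Increasing the cutoff can only decrease the number of encoded
motifs. Note the 6-nt minimum does not by itself guarantee an encoded RG
or GG dipeptide — that depends on where the overlap sits relative to codon
boundaries — so no such invariant is asserted.

Dataset agreement is reported as nucleotide-level Jaccard plus both
asymmetric containment fractions, optionally restricted to RGG coding
nucleotides, since a single agreed-upon metric is not fixed by convention.

## Genetic-code randomization

Three schemes, all holding the general structure of the code fixed:

* **codon_shuffle** — a uniformly random permutation σ of the 61 sense
  codons (stop codons are fixed points); the induced code
  `aa′(c) = aa(σ(c))` automatically preserves per-amino-acid codon counts.
  Sampling is permutation-uniform; distinct tables reachable by several
  permutations are weighted accordingly (no correction applied). CDS are
  re-translated, motifs re-detected with the identical grammar, rG4s stay
  fixed. Internal stops under randomized codes are kept as `*` (which can
  never sit inside a motif) rather than discarding transcripts, since
  discarding would distort motif counts.
* **arg_gly_assignment** — arginine and glycine are assigned to the full
  native codon boxes of two distinct amino acids; the 20 boxes are
  indivisible, giving 20·19 = 380 assignments (379 alternatives + native).
  Only R/G placement matters for the grammar, so the remaining residues
  collapse to a placeholder. Each draw carries a `gly_native` flag.
* **recoding** — each CDS is rewritten codon-by-codon with σ⁻¹ (protein
  and motifs fixed, UTR flanks fixed) and rG4s are re-*predicted*. The
  reverse statistic (fraction of predicted rG4s coding for a motif) and
  the per-code rG4 count are recorded alongside.

The empirical p-value is `#{f_null ≥ f_native} / n` with the native draw
excluded from the denominator (so 1 exceedance in 10,000 gives 0.0001 and
2 among the 379 alternative assignments rounds to 0.0053). Null draws use
per-code RNG substreams spawned from the master seed, so results are
reproducible and order-independent. The motif-length sweep reuses one set
of null translations across cutoffs; rows with an empty native motif class
are flagged undefined, and rows where no null code reaches the native
fraction are flagged explicitly.

## Synthetic transcriptomes

The generator emulates the pipeline's inputs with known truth: CDS of
normally distributed length (codon units) plus random ≤ 50-nt flanks;
planted motifs (Poisson count per transcript; lengths geometric above the
grammar minimum 4 with median 7, capped at 52, mimicking the observed
abundance of short motifs); linkers and 6-residue buffer zones drawn from
non-R/G residues so every planted motif is re-detected at exactly its
planted coordinates; per-sample expression tables with a configurable
failure fraction.

Codon choices: background residues default to a uniform amino-acid
alphabet with uniform synonymous codons (`background="uniform_aa"`);
`"uniform_codon"` instead draws sense codons iid uniformly, which makes
the sequence law invariant under any relabeling of the code — the property
the calibration experiment needs. Motif residues are drawn from the
guanine-richest synonyms with probability `g_bias` (uniformly over ties:
CGG/AGG for Arg, GGG for Gly), else uniform synonymous.

rG4 placement: in **association** mode each planted motif carries, with
probability `planted_rg4_rate`, an interval inside its own coding span
(length ≥ 6, covering 60–100% of the span) — the coding relationship
exists by construction. In **null** mode explicit G-tracts (configurable
tetrad count and loop lengths) are placed only in motif-free spans. Mock
experimental datasets apply independent noise per dataset — sensitivity
(dropout), per-kb uniform false calls, Gaussian boundary jitter clamped to
transcript bounds — and the RT-stop mock places one stop at the 3′ end of
each reported region.

What the generator does *not* emulate: real codon-usage bias, sequencing
depth and coverage structure, transcript families/paralogy, UTR
composition, or the biochemical specifics of reverse-transcriptase
stalling. Passing tests therefore demonstrate the correctness and
statistical behavior of the *method*, not the effect sizes expected on a
real transcriptome.

## Statistical calibration and power

**Calibration.** The association-free condition uses
`background="uniform_codon"`, no planted motifs or tracts, and uniform
false calls (5/kb) as the rG4 dataset, on 40 transcripts × 2,500 codons
per replicate. Because the background codons are iid uniform over the
sense codons and the calls are sequence-independent, the native statistic
is exchangeable with the null draws and the p-value is approximately
uniform; over 50 replicates (n = 99 each) a Kolmogorov–Smirnov sanity
bound (D < 0.25, around the 99.9th percentile for 50 uniform draws) is
asserted. Planting motifs would instead bias p low, because planted motifs
are longer than the spurious motifs of randomized codes and the encoded
fraction is length-sensitive — a real anti-conservativeness of this
statistic worth keeping in mind when interpreting it.

**Power.** At `g_bias = 1` with G4Hunter-predicted rG4s (association mode,
120 transcripts × 500 codons, ~50 planted motifs), the codon-shuffle
experiment at n = 200 yields p = 0 with a wide margin: the native code
encodes essentially all motifs, while each randomized code's fraction is
diluted by its own spurious background motifs. The *recoding* experiment
destroys the planted association as well, but its p can exactly tie at a
small rate: a permutation whose preimages of the few motif codon types are
themselves guanine-rich re-detects every fixed motif and reproduces the
native fraction (~1% of draws at maximal bias, where motif regions are a
near-monoculture of CGG/AGG/GGG). The recoding test therefore asserts
dominance (native ≫ null median, p ≤ 0.05) rather than exact zero; real
transcriptomes, with their heterogeneous codon usage inside motifs, do not
offer a single lucky preimage that rescues every motif at once.

Problem sizes throughout the suite (tens of transcripts, hundreds of
codons, n ≤ 200 null draws for the statistical tests) are desk-scale
analogues chosen so the full suite runs in seconds while leaving the
measured margins wide.

## Expression filters

* **CPM filter** (stalling-assay design, samples Li⁺ ×2, K⁺ ×2, K⁺+PDS ×2):
  a gene is kept iff ≥ 2 samples reach CPM ≥ 1 *and*, under the default
  grouped reading, the qualifying samples cover Li⁺ and at least one of
  K⁺/K⁺+PDS. The conjunction in this rule is ambiguous in ordinary prose,
  so the grouping is configurable and a plain any-two-samples reading is
  available (`grouped=False`).
* **TPM filter** (RT-stop design, one K⁺/Na⁺ pair per cell line): kept iff
  some cell line has TPM ≥ 0.5 in both its K⁺ and Na⁺ sample (inclusive).

Both are pure set operations: retained ∪ dropped = input, and the result
depends only on the table and thresholds.

## Profile correlation

The per-residue guanine-density profile is the fraction of G among the
nucleotides of the codons in an odd window (default 21 residues, clipped
at the termini) centred on each residue; the preference profile is the
window mean of a user-supplied per-residue scale. Pearson r between the
two is reported, or absent when either profile is constant. With an
affinity-like scale where lower values mean stronger guanine preference,
profile matching yields negative r.

## Known limitations

* The QGRS G-score is a native formula satisfying the published scoring
  principles, not a value-for-value reimplementation of the original tool;
  comparisons against external QGRS outputs should be rank-based.
* pqsfinder-style predictions are not implemented; such calls are consumed
  as BED via `ingest_bed`.
* All coordinates are transcript-space; no genome liftover is provided.
* Randomized-code sampling is uniform over permutations, not over distinct
  induced tables.
* The overlap statistic's length sensitivity (above) means its empirical
  p-values are calibrated only under exchangeable nulls; the motif-length
  sweep is the tool for separating length effects from code-structure
  effects.
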