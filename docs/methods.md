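# Methods

`elpcip` implements a probe-level strategy for separating *expression level
polymorphisms* (ELPs — heritable transcript-abundance differences between two
genotypes) from treatment responses on short-oligo expression arrays, in the
setting of a balanced two-genotype × two-treatment × r-replicate experiment
(e.g. two rice cultivars under oxidative stress vs. mock). This note records
the models, the defaults and why they were chosen, and what the synthetic
benchmark does and does not demonstrate.

## Statistical model

Each probe's log2 intensity is analysed with a fixed-effects two-way ANOVA

    y_gtk = μ + α_g + β_t + (αβ)_gt + ε_gtk ,   ε ~ N(0, σ²)

over genotype g ∈ {A, B}, treatment t ∈ {control, treated} and replicates
k = 1..r. With a balanced design the Type I/II/III sums of squares coincide
and the decomposition is closed-form:

    SS_G  = 2r Σ_g (ȳ_g − ȳ)²          (genotype / cultivar)
    SS_T  = 2r Σ_t (ȳ_t − ȳ)²          (treatment)
    SS_GT =  r Σ_gt (ȳ_gt − ȳ_g − ȳ_t + ȳ)²
    F_eff = SS_eff / (SSE / 4(r−1)) ,   p from F(1, 4(r−1)).

Unbalanced designs are rejected rather than approximated. Degenerate inputs
are defined, not left to float arithmetic: SSE = 0 with a zero effect SS
gives p = 1; SSE = 0 with a positive effect SS gives p = 0; both carry a
`degenerate` flag. Benjamini–Hochberg q-values are attached per effect
across probes for reporting, but the downstream gate uses raw p ≤ α
(default α = 0.01): the q-values quantify the multiplicity burden without
changing the calling rule.

A probe is a **core probe** when all three effects reach p ≤ α
simultaneously; a probe set is a **core intersectional probe set (CIP)** —
an ELP candidate that also responds to treatment, differentially by
genotype — when it contains at least `min_core_probes` (default 3) core
probes. Requiring several concordant probes per set is the multiplicity
control that matters here: under the null the triple intersection is rare
(~α³ per probe before correlation inflation), and three independent core
probes per set make a false set-level call rarer still (measured set-level
empirical FDR ≈ 0.06 at defaults).

Each CIP is placed in one of four expression quadrants by the signs of two
probe-set-level deltas on log2 signals: the genotype preference
(mean over genotype-A arrays − mean over genotype-B arrays) and the
treatment response (treated − control), each averaged over the other
factor. Judging "up-regulated" on the overall main effect rather than
within one genotype was a genuinely open choice; the main-effect version
is symmetric in the two genotypes and is what the generator's sign
convention guarantees to recover (below). A delta of exactly zero —
possible only on constructed inputs — yields `unclassified`.

## Preprocessing

Arrays are quantile-normalized at probe level: each column's sorted values
are replaced by the across-array mean of that rank; ties receive the mean
of the reference values of the ranks they occupy, so the operation is
deterministic and rank-preserving. Probe sets are summarized per array as
2^(20%-trimmed mean of log2 probe intensities) — a robust, fully specified
stand-in for proprietary one-step biweight summaries, adequate for arrays
without mismatch probes — and each array is scaled by one constant so its
2%-trimmed mean signal equals the target TGT = 500. The trim fractions
(20% within set, 2% across sets) are configuration constants; only the TGT
value is externally mandated. Replicate QC computes Pearson r on log2
signals for every within-condition array pair and flags pairs below 0.98;
a zero-variance array yields r = NaN with a degenerate flag rather than an
exception.

ANOVA consumes log2 quantile-normalized intensities. The log2 transform is
a deliberate fixed choice (variance stabilization standard for
fluorescence data) and is echoed in output metadata.

## Probe screen

A probe *hits* a genome when it or its reverse complement occurs ungapped
with at most `max_mismatch` mismatches (default 0; exact matching is the
reproducible baseline) on any sequence; a position matched by both
orientations counts once. Probes are classified `both` / `a_only` /
`b_only` / `neither`; the `both` fraction estimates how little of the
array is compromised by sequence-level polymorphism between the
genotypes. The implementation vectorizes a sliding-window comparison; the
hit definition, not the algorithm, is the contract, and tests hold it
against a per-position brute-force scan.

## Enrichment

Category over-representation of the CIP set uses the one-sided
hypergeometric upper tail P(X ≥ k) with the universe fixed to the items
annotated in the queried aspect, and BH correction across that aspect's
categories. Annotations are taken as provided — no ontology-graph
propagation — so the universe definition is explicit and testable.
Categories with no annotated members are skipped.

## Motif discovery

De novo discovery is seed-driven word enumeration with greedy refinement:
every w-mer (default w = 8, both strands) of the `top_t` highest-ranked
foreground sequences seeds a candidate motif from all foreground w-mer
instances matching it at ≥ m positions (default m = w − 2); candidates are
scored by

    score = log2(n) · (1/w) Σ_i Σ_b f_ib log2(f_ib / p_b),
    f_ib = (c_ib + 0.5) / (n + 2)

(n sites, counts c, 0-order background p estimated from the background
set, uniform if absent); the best `max_candidates` are refined by single
site additions/removals accepted only on strict score increase, bounded at
100 steps, then deduplicated by consensus. The procedure has no hidden
randomness; ties break lexicographically by consensus. The refinement uses
an exact incremental decomposition of the score (only the w touched count
cells are re-evaluated per move), which changes the cost, not the result.

Two behavioural notes. First, because both strands are searched, a planted
element may surface as its reverse complement; consensus identity should
be judged up to reverse complement. Second, the log2(n) prefactor lets
refinement grow weakly conserved site sets on pure background sequence to
substantial scores; planted motifs still separate from the null top score,
but the separation is a ratio of roughly 1.3, not an order of magnitude —
the score is a ranking device, not a calibrated significance measure.
Known-element scanning (`scan_iupac`, e.g. the W-box AGTCAAAC, the CGCG
box GCCGCGGC, TCTCTCTC) counts overlapping occurrences on both strands,
counting a position once when a strand-symmetric pattern matches both
orientations.

## InDel overlap

Coordinates are 0-based half-open internally; GFF3 and the 1-based
inclusive InDel table are converted at the boundary. An InDel is *genic*
when its interval overlaps the gene span (overlap takes precedence),
*upstream* when entirely on the strand-aware 5′ side within
`upstream_window` bp (default 1000 — the extent of "upstream" is not
externally defined and is exposed in configuration), *downstream*
symmetrically. Distances are 1-based boundary-to-nearest-base differences.
Classification is per gene–InDel pair, so one InDel near two genes
contributes to both. "Genic" is judged against the gene span, not exon
structure — a deliberate simplification given gene models without CDS
features. CIP genes carrying any classified InDel form the
ELP-with-sequence-polymorphism intersection.

## Synthetic scenarios

The generator emulates the statistical structure the analysis assumes, at
desk scale, fully reproducible from one integer seed (each sub-generator
draws from its own child stream, so adding one never perturbs another):

- **Genome pair** — i.i.d. genome A, genome B derived by recorded SNPs
  (per-bp rate chosen so ~5% of probes overlap a variant) and rare short
  indels; ground-truth variant list retained.
- **Probes** — 200 probe sets × 11 probes × 25 bp tiling gene bodies of
  genome A; a probe is truth-polymorphic iff its footprint overlaps a
  variant.
- **Intensities** — log2 signal = set baseline N(8, 1) + probe affinity
  N(0, 0.5) + planted effects + N(0, 0.3), emitted on the linear scale.
  10% of sets are planted ELPs with |Δ_genotype| = |Δ_treatment| = 1.5 and
  |Δ_interaction| = 1.0 (the interaction applied to the genotype-A-treated
  cell); signs follow the planted quadrant, drawn 645:101:223:93 — the mix
  of a stress response where genotype-A-preferred transcripts are mostly
  induced and genotype-B-preferred ones mostly repressed. The interaction
  sign is the product of the two main-effect signs, which keeps both
  measured main-effect deltas away from zero for every quadrant, so
  quadrant recovery fails only through noise, not construction.
  Polymorphic probes lose 2.0 log2 units in genotype B, emulating
  hybridization loss on the mismatched genome.
- **Annotations / promoters / InDels** — one category enriched among
  planted sets at odds 10 over a 10% baseline; one 200 bp promoter per
  gene with the W-box planted once in each planted gene's promoter; InDels
  placed near half the planted genes (10% of background genes) with
  region mix ~64:32:11 upstream:genic:downstream.

What passing tests show — and don't. The benchmark verifies the machinery:
calibrated type-I error (~0.011 at α = 0.01), essentially full power for
the main effects at the planted sizes, error-free quadrant assignment of
detected sets, correct enrichment ranking, motif recovery, and exact
interval classification. It does not emulate spatial array artifacts,
probe-sequence affinity bias, cross-hybridization, or correlated noise,
so absolute sensitivity numbers do not transfer to real chips. One
interaction of the defaults deserves emphasis: an indicator interaction of
1.0 log2 at σ = 0.3, r = 3 has noncentrality 8.3, i.e. per-probe power
only ≈ 0.39 at α = 0.01, and quantile normalization further compresses the
planted extreme cells; end-to-end sensitivity at these defaults is
therefore ≈ 0.46, with empirical FDR ≈ 0.06. Detecting ≥ 90% of such sets
would require an interaction near 2.0 log2 units or more replicates — a
property of the triple-significance design itself, which buys its low
false-call rate with conservative power on weak interactions.

## Problem sizes

Default test and benchmark sizes — 200 probe sets (2,200 probes), 12
arrays, 10 scenario replicates, 1,000-probe calibration matrices, 5 kb
screen genomes, 20 × 200 bp promoter sets — were chosen as the smallest
scales at which the binomial/normal sampling error of each measured rate
is well below the margin being asserted.
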