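# Methods

This note documents the statistical machinery, the simulator that stands in
for population data, the numerical conventions, and the limits of what the
test suite demonstrates.

## Genetic code and synonymous families

All downstream statistics derive their degeneracy structure from a single
embedded code table keyed by NCBI translation-table number. The default is
the vertebrate mitochondrial code (table 2): 60 sense codons, 4 stop codons
(UAA, UAG, AGA, AGG), and synonymous families of sizes 2 (12 families),
4 (6 families: Ala, Arg, Gly, Pro, Thr, Val) and 6 (Leu, Ser). The standard
code (table 1) is included only to support the ENC compatibility mode and
to exercise code-dependence in tests. Codons are held internally in the RNA
alphabet; T→U normalization is idempotent and inverted on DNA output.

Two conventions are deliberately exposed as flags rather than fixed:

- **Six-fold families.** RSCU can treat mito Leu/Ser as single six-fold
  families (default, strictly code-derived) or split them into their
  four-fold and two-fold third-position boxes (`split_sixfold=True`),
  since codon-usage software differs silently on this point.
- **Stop codons.** For RSCU display the four stops form a pseudo-family of
  degeneracy 4, so stop-codon preference is part of a gene's profile;
  stops are *always* excluded from ENC (class membership is undefined) and
  from GC3 by default.

## CDS handling

CDS are analyzed in mRNA sense; minus-strand genes (canonically ND6) are
reverse-complemented on read, so their mirrored skew/PR2 behaviour emerges
from composition rather than from special-casing. Incomplete terminal stops
(1–2 nt, completed in vivo by polyadenylation) are dropped from the codon
list by default (`stop_policy="drop-partial"`); `"polyadenylate"` completes
the tail with A's to a stop codon for complete-stop accounting. The default
keeps every counted unit a true codon: a 1378 bp gene yields exactly 459
codons. An internal stop is treated as a hard error (misannotation), and a
CDS length that is not a multiple of 3 despite a complete annotated stop is
flagged by input validation rather than silently truncated. Codons
containing ambiguity codes are excluded from counts with a logged tally.
Coordinates are 1-based inclusive on the way in (GenBank convention, with a
0-based half-open option), 0-based half-open internally, converted in one
place.

## RSCU, CUP classes, CAM

For codon *j* in family *i* of size k<sub>i</sub> with family total
N<sub>i</sub> > 0, RSCU<sub>ij</sub> = k<sub>i</sub>·n<sub>ij</sub>/N<sub>i</sub>;
family sums then equal family sizes exactly, and the statistic is invariant
to sequence duplication. A family with zero observations yields flagged
missing values (NaN), not zeros — but its members still have usage count 0,
so they classify as *unused* and belong to the gene's codon aversion motif
(CAM) by default; `include_unobserved_families=False` restricts the CAM to
observed-family zeros. CUP thresholds: unused (RSCU = 0), under-represented
(0 < RSCU < 0.6), over-represented (> 1.6), unbiased otherwise; boundary
values 0.6 and 1.6 are unbiased.

Population profiles are mean-then-classify: per-gene RSCU is averaged
across individuals (NaNs ignored per codon) and CUP classes are assigned to
the means. The interval summary tallies every (gene, codon) pair — grand
total #genes × 64 — into the four CUP intervals split by third-position
nucleotide; printed percentages use round-half-up to 2 decimals, matching
the convention of published tables, while TSV outputs keep full precision.

Per-gene RSCU profiles (64-dimensional, family-absent values imputed as 0
with a log note) are clustered agglomeratively; defaults are Euclidean
distance with average linkage, chosen for determinism and robustness and
both configurable, with the dendrogram exported as Newick. Published
five-group partitions of the 13 PCGs depend on the underlying data and are
not treated as a binding expectation.

## ENC and the ENC-plot

Wright's estimator: per observed family with n ≥ 2,
F = (n·Σp<sub>j</sub>² − 1)/(n − 1); F-values are averaged within
degeneracy classes, and ENC = Σ<sub>s</sub> N<sub>s</sub>/F̄<sub>s</sub>
over the code's class structure. Families with n < 2, or with F = 0 (all
observed codons distinct — no homozygosity signal), are excluded from class
means, following CodonW's convention. A class left without any estimable
family is interpolated from its neighbouring classes (the classic
F̄₃ ≈ (F̄₂ + F̄₄)/2 device generalized to nearest observed classes) and the
result flagged `interpolated`. Small-sample F can legitimately fall below
1/k (e.g. counts 2/1/1/0 in a four-fold family give F = 1/6), so the code
asserts F ∈ [0, 1]; the F ≥ 1/k bound only holds asymptotically.

Two modes:

- **code-derived** (default): the mito code's own structure,
  ENC = 12/F̄₂ + 6/F̄₄ + 2/F̄₆, theoretical range [20, 60];
- **standard-compat**: the same family F-values combined with the standard
  code's class structure, ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ (F̄₃
  interpolated), capped at 61. This exists because widely used tools print
  mitochondrial ENC values up to 61, which is impossible under the strict
  mito family structure; with the interpolated three-fold class the
  zero-bias limit of this mode is ≈ 60.67, and values approach 61 only
  through small-sample noise before capping.

ENC is capped at the mode's maximum; the ≥ 20 bound holds automatically
since F ≤ 1. GC3 is the G+C fraction at third positions over all sense
codons (stops excluded); a synonymous-only variant is provided for codes
with single-codon amino acids (a non-issue under the mito code). The
standard curve evaluates ENC\* = 2 + GC3 + 29/(GC3² + (1−GC3)²) on an
inclusive grid (default step 0.001, 1001 points). Note the curve equals
exactly 60.5 at GC3 = 0.5 but its true maximum is marginally higher
(≈ 60.5011 near GC3 ≈ 0.509) because of the linear term. The per-gene
`below_curve` flag compares ENC to ENC\*(GC3) minus a configurable margin
(default 0).

## PR2 bias

Per gene, the third positions of its four-fold degenerate codons give
counts A3/T3/G3/C3 and biases A3/(A3+T3), G3/(G3+C3); both equal 0.5 under
strand-symmetric mutation and selection. Plot convention (fixed here, since
the literature often leaves it implicit): x = GC-bias, y = AT-bias,
quadrants counted counter-clockwise from (+,+), so quadrant II is the
A-and-C-preferring corner typical of heavy-strand mito genes and quadrant
IV the G/T corner where a light-strand gene lands. A point with either
coordinate exactly 0.5 or undefined (zero denominator) is labelled
`on-axis` rather than forced into a quadrant. Genes contributing fewer than
10 four-fold codons carry a low-support flag — at ~20 total codons a
two-decimal bias is sampling noise. Population-level points pool four-fold
codons within gene across individuals by default; a per-individual option
exists.

## The population simulator

The generator emulates the structure of a conspecific mitogenome
population: 13 PCGs with realistic cervid lengths, strands, start codons
and stops (ND6 on the minus strand; ND4 ending in `T`; one reported
1546 bp COX1-type length is not a codon multiple and is replaced by 513
whole codons), tRNA-sized spacers, an rRNA-sized block and a
control-region-sized AT-rich filler, and n individuals (default 89)
derived from a common ancestor.

Codon usage is modelled at the codon level — every downstream statistic is
a codon-table functional — as (amino-acid marginal) × (within-family
conditional). Presets:

- `kansuensis-like` (default study conditions): third-position weights
  A:C:U:G = 8 : 3.5 : 2 : 0.5 on the heavy strand (complement-mirrored for
  ND6), per-gene family conditionals drawn from a Dirichlet centred on
  those weights (concentration 40 by default; the Dirichlet mean is the
  base conditional, so the recorded truth is the realized draw), and
  per-gene amino-acid jitter around a hydrophobic-rich profile with floors
  keeping all 20 families represented. These weights were chosen once to
  produce the canonical heavy-strand pattern (positive AT-skew, negative
  GC-skew, PR2 quadrant II, strong A-ending preference) at realistic
  magnitudes.
- `neutral`: uniform conditionals — RSCU truth 1 everywhere;
- `strand-symmetric`: equal A/T and G/C third-position weights and no
  jitter — the PR2 null;
- `extreme-bias`: one codon per family (start codons aligned to the Met
  family's pick so the single-codon property is exact) — ENC = 20 by
  construction.

Individuals receive Poisson(μ·L) substitutions (μ default 0.001/site,
bounded at 0.05 — realistic intraspecific mitogenome divergence is a few
SNPs per 10 kb) that resample the hit codon *within its third-position
synonymous box* using box-renormalized conditionals. This choice makes
divergence synonymous-only (protein sequences identical across individuals)
and exactly marginal-preserving, so the generator's expected codon
frequencies remain the truth for the mutated population. A `messy` flag
allows nonsynonymous resampling from the gene's full sense distribution.

A subtlety that matters for interpreting recovery tests: a population of
near-identical genomes carries essentially *one* genome's worth of sampling
information, however many individuals it contains. Mean-RSCU and PR2
recovery checks therefore either (a) draw independent genomes from one
resolved truth distribution via `generate(spec, generation_seed=...)` —
89 independent genomes give > 5000 pooled codons in every family, where a
±0.1 per-codon tolerance is comfortably valid — or (b) compare the
common-ancestor population's mean against the pooled single-ancestor value,
which is the quantity it actually estimates. Randomness is integer-seeded
through `numpy.random.default_rng` with fixed stream tags, so output is
reproducible across platforms.

What the simulator does **not** emulate, and hence what passing tests do
not show about real data: tree-structured divergence between populations or
subspecies, within-gene spatial structure (codon draws are i.i.d., so no
conserved motifs or domain effects), overlapping genes, tRNA/rRNA biology,
sequencing or assembly error, and any mutation–selection dynamics beyond
the static usage distribution. Qualitative agreements with published
population patterns demonstrate that the statistics behave correctly, not
that the simulator is a model of elk mitogenome evolution.

## Problem sizes and runtime conventions

Default analyses run on 89 genomes × 13 genes (~3800 codons per genome) in
seconds. Oracle-equivalence tests use 100 seeded random count tables per
statistic and 30 random instances (4–7 leaves) for clustering, sizes at
which exhaustive brute-force re-computation is exact and fast. The ENC
monotonicity check uses five Dirichlet concentrations spanning 0.3–100 with
per-gene ENC as Spearman pairs.

## Known limitations

- ENC compatibility with any specific external tool is approximate: tools
  differ in F̄ exclusion rules, interpolation and capping; both modes here
  are exactly specified instead.
- Mean-then-classify CUP summaries depend on the averaging order; pooled
  counts across individuals are available but not the default.
- The clustering dendrogram is deterministic for distinct merge distances;
  exact ties fall back to implementation order of the linkage routine.
- `standard-compat` ENC cannot reach exactly 61 in the zero-bias limit
  (see above); published 60.95–61 values for short genes arise from
  small-sample noise under that convention.
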