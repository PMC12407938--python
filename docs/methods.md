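# Methods

This note records the models, parameter choices and numerical conventions
the package implements, the design decisions taken where the procedure was
genuinely open, and what the synthetic generator does and does not
emulate.

## Coordinate and data conventions

All intervals are 0-based half-open internally; GFF3 input is converted on
read, BED-family formats pass through. Contact dumps are per-sample
intrachromosomal triplets (`chrom pos_i pos_j value`) at one resolution,
with positions equal to bin starts; rows are canonicalised to the upper
triangle, duplicate bin pairs are rejected, and rows with non-finite
values (matrix-balancing artefacts) are dropped with a counted warning —
equivalent to treating them as unobserved, which matches the sparse
semantics used throughout (an absent entry is a true zero). Strand is read
but ignored downstream; all gene-pair and loop logic is orientation-free.

## Gene-pair interaction classification

The pair universe is every unordered same-chromosome combination of
reference-species genes that (i) have one-to-one orthologs in both other
ingroup species and the outgroup and (ii) whose orthologs are
co-chromosomal in all three ingroup species (pairs that cannot possibly
interact in some species are uninformative about conservation). An
optional separation cap (`max_separation`) and an "observed-only" universe
(pairs with at least one sparse entry) are available but off by default;
with full matrices both universes coincide, and the all-combinations
default is what yields the dominant "not conserved" class.

A pair's per-species value is the arithmetic mean of KR weights over every
bin pair the two genes occupy (genes spanning several bins contribute each
occupancy once; bin pairs lacking genes on either side contribute
nothing; a single gene spanning both bins yields no self-pair). The
interaction threshold is T = 10 KR-normalised reads, *inclusive* ("at
least"); raising T can only demote pairs, never promote them
(monotonicity is property-tested). Patterns the four categories do not
cover (e.g. one decapod only) are counted as UNCLASSIFIED and excluded
from category analyses. Distances are downstream-gene start minus
upstream-gene end and may be negative for overlapping genes; negative
values are retained and reported. Outgroup distance classes use inclusive
upper bounds (≤5 Mb; >5 and ≤15 Mb; >15 Mb).

For single-gene analyses (τ, family enrichment), interacting categories
keep all member genes while the non-conserved class keeps only genes
appearing in *no* interacting pair, preventing the background class from
being contaminated by genes that do participate in conserved contacts.

## Insulation

The score is a sliding-square statistic: `raw(i)` is the mean of the
`w × w` block of matrix entries connecting the `w` bins upstream of `i`
with the `w` bins downstream (the diagonal is excluded by construction,
`a < i < b`), and `score(i) = log2(raw(i) / chromosome mean of raw)`.
Bins whose square leaves the chromosome are missing, so exactly the first
and last `w` bins carry no score; an all-zero chromosome is entirely
missing. This contract reproduces the standard sign convention (boundary
minima negative, compartment interiors positive) and is frozen against a
brute-force oracle rather than any particular external implementation,
whose optional imputation/geometric-mean variants are deliberately not
reproduced. A raw value of exactly zero with a positive chromosome mean
gives −∞ — the chromosome minimum, which is the correct reading of a
contact-free seam — rather than being converted to missing.

Pair-level insulation is the mean of non-missing scores over the bins from
the one containing the upstream gene's last base through the one
containing the downstream gene's start (a shared bin for adjacent genes);
an all-missing span is missing and classes as NA. Classing at t = 0.2:
≥ t in all species → within domains; ≤ −t in all → boundary in all;
≥ t in the decapods but ≤ −t in the octopus (or vice versa) →
lineage-specific boundary; anything else, including the (−t, t) dead
zone, → OTHER. The window default is 350 kb (3 bins at 100 kb), chosen to
resolve loop- and domain-scale structure; windows are floored to whole
bins and a window under one bin is a configuration error.

## Loops

Multi-resolution merging treats a coarse call as a duplicate when *both*
anchor start positions lie within ±50 kb of a fine call's on the same
chromosome — anchor-wise and symmetric. Gene association requires at
least one gene overlapping each anchor; gene-less loops are retained for
coordinate analyses but excluded from conservation. Loops with identical
associated-gene sets (the canonical sorted union across both anchors) are
collapsed to the outermost coordinates, which can only grow the size.
Outlier removal mimicking manual inspection is available as an explicit
size cap, off by default.

Conservation between two species requires one orthologous gene per
anchor, anchors matchable in either order; a single gene's ortholog
cannot satisfy both anchors (so a gene spanning both anchors of both
loops does not by itself make them conserved). The stricter reading was
chosen over allowing both orthologs in one anchor of a nested partner;
the relation is symmetric and property-tested as such. Multi-way
conservation assembles the pairwise matches into connected components;
each component is one "conserved loop" observation, its per-species size
the mean over that species' member loops. The scaling statistic is the
per-component OLS slope of size (bp) on genome size (bp) — for two
species, Δsize/Δgenome — with a two-sided one-sample Wilcoxon signed-rank
test of the slope distribution against zero. Components whose member
genome sizes are all equal are skipped with a warning; an identically-
sized component contributes an exact zero slope.

Context overlap (developmental stages, tissues) uses gene-set identity
for gene-associated loops and (chromosome, anchor-1 start bin, anchor-2
start bin) identity for all loops at a common resolution. Each context
pair gets hypergeometric enrichment and depletion p-values over the
universe of identity keys pooled across *all* supplied contexts (a global
universe keeps the tests for different pairs comparable), with BH
correction across pairs.

## Expression metrics

TPMs are transformed as log2(TPM + 0.01); the pseudocount stabilises
variance at zero, the base is configurable and affects neither orderings
nor Pearson correlations. τ is computed on the linear scale by default —
the index is scale-invariant there and stays in [0, 1] — with a log-scale
variant (negatives floored at zero, then clipped) for compatibility with
pipelines that compute τ after log transformation; both modes are tested.
Pearson r is undefined when either gene has zero variance, so such pairs
are dropped with a logged count — a deliberately stricter rule than
excluding only both-flat pairs, which would leave r undefined.
Between-category comparisons use two-sided Wilcoxon rank-sum tests under
BH correction; family enrichment uses two-sided Fisher exact tests on the
2×2 table of category × family membership over the annotated universe,
BH-corrected within each family's series independently.

BH adjustment is the standard step-up with running-minimum monotonicity,
order-preserving, delegated to statsmodels and cross-checked in the test
suite against a hand-rolled implementation.

## Region partitions and enrichment

Anchors are the merged union of all anchor intervals; interloop spans are
the merged (anchor1 end, anchor2 start) gaps minus any anchor overlap;
background is the exact complement — the three classes are disjoint and
sum to the genome size to the base pair (asserted in tests). Each merged
interval is one statistical observation for the rank tests, matching the
per-region framing of interval-coverage tools; a CNE is counted once in
every region it overlaps, with no fractional attribution. Open-chromatin
peaks are signal intervals strictly above 1.0 (a value of exactly 1 is
not a peak); per-region coverage is the covered *fraction* by default
with a count mode available, since the upstream tooling supports both.
Accessibility tracks are assumed pre-scaled across conditions.
Intervening-gene coverage is the percentage of a gap covered by the union
of genes overlapping it, after dropping genes over 1.5 Mb as likely
misannotations; empty, negative (overlapping flanks) and gene-free gaps
are excluded with logged counts. Repeat composition divides per-class
repeat counts by intergenic length, sums densities per category, and
rescales to percentages summing to 100; pairs without any repeat are
excluded.

## Chromosome homology, windows, dispersion

No principled fold-enrichment rule exists for calling homologous
chromosome pairs when chromosomes are few: the contingency expectation
for a perfect 1:1 pair is row·col/total, so the attainable fold is capped
at total/row and a fixed multiple-of-expectation test cannot even call
the identity pairing on clean data. The rule used instead is a binomial
tail test: pair (a, b) is homologous when it shares ≥ `min_share`
orthologs (default 5 at toy scale; a few dozen is appropriate at genome
scale) and `P(X ≥ count | X ~ Bin(row_a, col_b/total)) < 1e-4`. A
shuffled ortholog table essentially never produces a call, true homologs
are astronomically significant, and one-to-many calls (fissions, fusions)
fall out naturally. The α default leaves ~0.1 expected false pairs even
over a 30×30 chromosome grid.

Windowed homology tiles each chromosome (last window truncated); window
*u* maps to window *v* in the partner species when ≥ 3 of *u*'s genes
(configurable) have their ortholog in *v*, and windows are summarised as
unmapped / single / multi in both directions — the direction asymmetry is
what distinguishes fusion from fission. Dispersion counts each alignment
block (≥ 100 bp after filtering) once, homologous iff its chromosome pair
is in the homology map; chromosomes absent from the map count as
non-homologous with a warning. CNEs are non-coding blocks (zero overlap
with coding intervals — CDS when available, else gene spans — where 1 bp
of overlap makes a block coding) of ≥ 100 bp, relaxed to ≥ 50 bp when
testing orthology of an established CNE to a third species.

## The synthetic world

The generator is a stated world, not a tuning knob; its defaults are
frozen and every recovery test runs against them.

* **Genomes.** Four ancestral (outgroup) chromosomes × 300 genes
  (1,200 ortholog sets), 10 kb genes, 100 kb resolution. Ingroup genomes
  derive from the ancestral order by per-lineage fission/fusion events
  with optional within-chromosome shuffling (fusion-with-mixing); the
  default plans fuse c1+c2 in both decapod lineages and additionally
  c3+c4 in the octopus lineage, the more derived karyotype. Genome sizes
  (120 / 110 / 60 Mb ingroup, 60 Mb outgroup) keep the real system's
  qualitative ordering — large decapod genomes, compact octopus and
  outgroup — by scaling intergenic gaps at constant gene count.
* **Contacts.** Expected value c·max(s,1)^−α with α = 1 and c = 30 at
  one-bin separation, ×3 inside planted compartment blocks (alternating
  ~25-bin blocks with ~6-bin seams), plus planted loop strength at anchor
  bin pairs. Realised values are Gamma(shape k = 4, mean = expectation):
  non-negative and overdispersed, a reasonable stand-in for balanced
  Micro-C weights. With k = 4, a planted mean of twice the threshold
  would clear T = 10 in all three species only ~63% of the time
  (Q(4, 2)³), so the default planted strength is 60 KR units — six-fold
  over threshold, in line with focal loops standing several-fold above
  local background — giving ~98.5% three-species recovery a priori. The
  loop boost covers every bin pair the two anchor genes occupy, so
  bin-straddling genes do not dilute the averaged pair value.
* **Loops.** Twelve conserved loops planted at ortholog pairs
  co-chromosomal in all ingroup species (30–90 ancestral genes apart),
  plus four species-private loops per ingroup species; call files are
  emitted at 100 kb, with the first two loops re-called at 50 kb so
  multi-resolution merging always has duplicates to drop. Loop *sizes*
  are whatever the rearranged gene spacings imply — the world plants no
  systematic size–genome-size scaling, so the demo's signed-rank slope
  test is expectedly non-significant; the power of that statistic is
  established separately on simulated slope distributions.
* **Expression.** 19 tissues (a typical adult tissue panel). Log-normal
  TPMs (log-mean 2, log-sd 1); planted interacting pairs share a
  bivariate normal on the log scale with ρ = 0.6 (strong but not
  extreme co-regulation); a handful of all-zero genes exercise the
  zero-variance path.
* **CNEs, repeats, accessibility.** 1,000 CNE blocks (120–400 bp) placed
  intergenically with a 0.30 probability of landing on a non-homologous
  partner chromosome (0.15 for 300 coding blocks — coding sequence
  disperses less); 2,000 repeats over five classes; a 5 kb-tiled
  accessibility track with Gamma baseline (mean 0.5) boosted 2.5× inside
  anchor regions.
* **Truth ledgers** for planted loops, compartments, pairs and blocks are
  always emitted, and a fixed seed reproduces every output byte.

What the world does *not* emulate — and hence what a green test does not
establish: mappability and assembly artefacts, balancing biases,
resolution-dependent loop-calling noise (calls are planted, not called),
trans contacts, realistic gene-length and gene-density variation,
lineage-specific gene loss (the ortholog table is complete), and
expression compositionality. Recovery results certify the pipeline's
logic, not the upstream callers.

## Pipeline and numerical choices

Stages run in dependency order; every output is TSV with `%.8g` floats,
and the manifest records parameters (no filesystem paths, so manifests
are byte-reproducible) plus SHA-256 hashes of inputs and outputs. The
quadratic per-pair analyses (co-expression, intervening genes, repeats)
run on all interacting pairs plus a seeded subsample (default 2,000) of
the dominant non-conserved class; classification itself always uses the
full universe. Wilcoxon tests fall back to exact or asymptotic forms as
scipy chooses; equality comparisons against thresholds are exact
(`>= T`, `<= −t`, `> 1.0`) with no epsilon, matching the inclusive /
strict wording of each rule. Oracle comparisons in the tests use 1e-9
absolute tolerance; determinism tests compare SHA-256 of whole files.

## Known limitations

Conservation components can chain distinct loops through a shared partner
(A–B and B–C merge even if A and C share no orthologs); at realistic loop
densities this is rare, and the component-level size averaging keeps the
slope statistic well-defined regardless. The homology binomial test
conditions on marginal counts and ignores intra-chromosomal gene order;
micro-rearrangements invisible at the chromosome scale do not affect it.
The insulation contract fixes one specific normalisation; scores from
tools with imputation or geometric means are comparable in sign and rank
but not numerically identical. The hypergeometric overlap universe is the
union of observed identity keys, which understates the universe when many
loops are callable but absent everywhere — enrichment p-values are
conservative in that regime.
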