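# Methods

This note documents the models, rules and numerical choices behind
`circuitcall`, what the synthetic-data generator does and does not
emulate, and where the design was genuinely open.

## Coordinate conventions

All in-memory coordinates are 0-based half-open; narrowPeak and BED are
already 0-based on disk, so readers and writers perform no shifting.
narrowPeak column 9 carries −log10(q) per the ENCODE dialect and is
converted to a linear q-value in (0, 1] on read; a summit offset of −1
falls back to the interval midpoint and flags the peak, since downstream
logic is entirely summit-based. Wherever a "nearest" entity is computed,
ties break to the lexicographically smallest gene id, which makes every
operation deterministic under input permutation.

## Peak filtering and overlap

KO cells for a factor should carry none of that factor's genuine binding,
so peaks called (leniently, q ≤ 1e-2) in the KO sample mark non-specific
sites. A WT peak is discarded iff a KO summit lies within 300 bp on the
same chromosome — deliberately the same summit-distance convention used
for peak-set overlap, so one geometric rule governs both operations. WT
confidence tiers are per-factor q-value cutoffs (T 1e-4, pSmad1/5 5e-4,
pSmad2 1e-7, Eomes 5e-4, pluripotency factors 1e-4). Venn membership is
per peak ("any opposite-set summit within 300 bp") and counted per input
set; when one peak matches several opposite peaks the two "both" counts
can differ, and both are reported rather than collapsed into matched
pairs.

## Gene assignment and direct targets

A summit inside any promoter window (TSS ± 2 kb) is promoter-associated
and assigns to every such gene. Every remaining summit assigns to the
gene with the nearest TSS to its left and the gene with the nearest TSS
to its right, in genomic coordinate orientation — distances are measured
to TSS points, not window edges, and strand is not consulted, since the
geometry is summit-to-promoter. Distal means > 10 kb from the nearest
TSS.

Differential expression is a pure threshold rule on replicate-averaged
FPKM: max FPKM > 1 in at least one sample of the comparison and
|log2 fold change| > 1, with a pseudocount of 0.1 added to both condition
means before the log. The pseudocount bounds fold changes for dropout
genes without materially moving genes that pass the FPKM floor (the
floor dominates: at means ≥ 10 the induced log-ratio error is < 0.01).
No test statistic and no multiple-testing correction are applied —
the rule is the method. Direct targets are the intersection of the
bound-gene set with the DE set, split by direction (activated = higher
in WT).

## Differential accessibility

The DA caller operates on counts-per-million against declared library
sizes: a region is DA iff |log2((CPM_WT + 0.5)/(CPM_KO + 0.5))| ≥ 1 on
condition means, max mean CPM ≥ 10, and the pseudocounted log-ratio has
the same sign for every WT × KO replicate pair. The sign-consistency
veto stands in for replicate modelling: with two replicates per
condition it removes regions whose apparent change rests on a single
outlying sample. This simple caller is a declared design choice — the
pipeline's downstream logic (occupancy grouping, activated fractions,
density dynamics) needs a deterministic, documented rule, not a
dispersion model.

Occupancy classification asks which ChIP summits fall inside a DA
region's interval and maps the answer onto six disjoint labels:
Smad1/5-solo, Smad1/5/2, Smad2-solo, OSN (all of Oct4, Sox2, Nanog),
O/S/N (one or two of them), none. Smad occupancy takes precedence over
pluripotency occupancy when both are present, reflecting that the Smad
categories are the analysis subjects; the same summit-in-region rule
serves Eomes/T overlays through configuration rather than separate code.

Accessibility density is (reads overlapping the region) / (region length
in kb × library size in millions), with any-base overlap; an optional
symmetric read-extension parameter emulates fragment extension and
defaults to 0 for synthetic reads. The statistic for group differences
is the paired two-tailed Student's t-test, t = mean(d)/(sd(d)/√n) with
df = n − 1; identical pairs return p = 1 flagged, and nonzero constant
differences report p at the machine floor with a zero-variance flag
rather than raising.

## Expression clustering

Genes bound by T and differentially expressed in the single T KO are
combined with those DE in the Eomes/T double KO; the union is clustered
with Lloyd k-means, k = 7, best of 25 restarts under a fixed seed.
Profiles are genotype means, log2(mean + 1)-transformed and then z-scored
per gene. The log transform is the consequential choice here: z-scoring
raw FPKM lets multiplicative noise on the highest-expression genotype
dominate the profile shape (planted-archetype recovery collapses to
ARI ≈ 0.4), whereas log-compression recovers the archetypes at
ARI ≈ 0.98. Constant profiles z-score to zeros and are flagged. Cluster
labels are renumbered by descending mean standardized WT expression so
reported labels are stable across the clusterer's internal permutations.
Cluster tags (both-required, Eomes-only, T-only, either-sufficient,
repressed, mixed) are a rule-based formalization over per-cluster
fractions of genes down/up in each KO, with a configurable 0.75
fraction threshold.

## The synthetic-data generator

The generator emulates the study design, not the raw data: a toy genome
(6 chromosomes × 2.6 Mb, 600 evenly spaced genes with jitter), per-TF
peak sets for WT and KO genotypes, one expression table across WT and
four KO genotypes, and accessibility counts over a day 0–3 time course
with the WT-vs-KO comparison at day 2. Two replicates throughout.

Planted structure and defaults:

- co-occupancy loci (each also an accessibility region, 600 bp): 40
  Smad1/5/2 pairs placed with summit separation < 300 bp, 30 + 30 solo
  Smad loci, 20 OSN, 20 O/S/N, 20 unbound;
- direct targets per TF (25/25/20/20) receive promoter peaks and
  multiplicative FPKM effects of 2^±2 (70 % activated), on a lognormal
  baseline with median ≈ 10 FPKM and log2-scale replicate noise of
  0.25 sd; ten further T-bound genes carry effects only in the double
  KO (cooperative regulation);
- 10 % of each factor's peaks are planted false positives that reappear
  (shifted < 300 bp) in the KO sample; KO-dependent peaks additionally
  leak into the KO file with probability 0.05;
- 60 % of regions are DA, with group-wise activated fractions of
  0.85–0.9 for Smad groups and 0.2–0.5 otherwise; counts are Poisson at
  baseline depth ≈ 50 (Gamma-distributed per region, floored at 15),
  with activated regions following a transient opening profile that
  peaks at day 2; library sizes are declared at 10^6;
- decoy DE genes (12 per comparison) are chosen only among genes
  *provably unbound* under the package's own assignment rule, and distal
  locus anchors avoid effect genes on both flanks. These two
  construction guarantees are what make noise-free recovery exact:
  with noise parameters at zero, direct-target precision and recall are
  1.0 by construction, the KO-discarded set equals the planted
  false-positive set, and DA occupancy labels equal the planted groups.

What the generator does **not** emulate: read-level sequence content,
mappability and artifact regions, fragment-size distributions,
peak-shape heterogeneity, correlated replicate structure, and the
gene-density irregularity of a real genome. Passing recovery tests
therefore demonstrates the correctness and calibration of the inference
rules under the declared noise model — not performance on real
sequencing data, where peak callers and count dispersion contribute
additional error.

The clustering archetypes are generated separately: seven standardized
(zero-mean, unit-variance) response shapes over (WT, Eomes-KO, T-KO,
double-KO), scaled to `separation × noise_sd` (default 4 sd) and
perturbed with genotype-level Gaussian noise on the log2 scale.
Standardized shapes keep "separation in sd units" meaningful in the
space the clusterer actually sees.

## Problem sizes and runtime choices

The default synthetic study (600 genes, ~540 peaks across four factors,
160 regions, 10 expression samples) runs the full chain in about one
second; oracle-equivalence checks use 20 random fixtures of ~100–250
peaks against brute-force O(n²)/O(n·m) scans. These sizes are chosen so
the whole validation suite is desk-scale while every code path
(promoter and distal assignment, both Venn roles, all six occupancy
groups, all seven archetypes) is exercised.

## Known limitations

- The DA caller has no dispersion model; with many replicates the
  sign-consistency veto becomes overly strict, and with one replicate
  per condition it is vacuous.
- Occupancy precedence (Smad over pluripotency) is a convention; regions
  genuinely co-occupied by both classes are reported under the Smad
  label only.
- DA regions are associated to genes by midpoint TSS distance classes
  (≤ 2 kb, 2–10 kb, > 10 kb) plus the standard assignment rule applied
  to midpoints; no enhancer–promoter contact information is used.
- The pipeline is single-process and memory-resident by design; inputs
  of desk scale are assumed.
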