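# Methods

## Data model

A pangenome graph is stored as nodes (uppercase DNA segments with an
rGFA rank and, for backbone segments, an `SN`/`SO` origin), directed
oriented edges, and a per-chromosome ordered backbone of rank-0 nodes.
The invariants enforced on read are: node length equals sequence length,
rank 0 holds exactly for backbone membership, backbone offsets are the
prefix sums of backbone node lengths (strictly increasing), and every
edge endpoint exists. Internal coordinates are 0-based half-open
everywhere; the two places that need another convention — VCF emission
(1-based, shared anchor base) and the virtual-SNP breakpoint test
(1-based inclusive `[s, e]`) — convert explicitly at the boundary.

Each assembly is represented by one oriented node path per chromosome
(a BED-like record). Orientation is honored when paths are read, but
occupancy accounting ignores it: a node visited in "−" is still carried.
The reference backbone is treated as one more carrier path (`REF`), which
makes the node partition exhaustive:

* **core** — carried by every assembly and the reference;
* **flexible** — carried by at least one but not all members of the
  universe;
* **nested** — carried by nothing (off-backbone, linked into no path).

Nested nodes model a known realignment artifact of backbone-anchored
graph builders: nodes constructed from some assembly's sequence that the
realignment step fails to re-traverse. They are excluded from NRS/NRUI
and all downstream analysis.

## SV calling

Projection walks a path and records its backbone visits; visits must be
collinear with backbone order, and out-of-order visits flag the path
while the offending segment is skipped and logged. A deviation event is
a pair of consecutive backbone visits with off-backbone nodes in between
and/or skipped backbone nodes. Events from all samples are pooled and
merged whenever their anchor intervals share interior backbone nodes
(union anchors, logged); events that only share an anchor node remain
separate bubbles. Within a bubble, each covering sample's allele is the
concatenated sequence of its nodes strictly between the anchors; alleles
are deduplicated by that sequence (no fuzzy merging of near-identical
alleles), alternative alleles are ordered deterministically by (length,
sequence), and samples that do not cover both anchors are genotyped
missing — not reference.

Classification, with `min_sv_len = 50` and `small_allele_tol` (default
0): INS when the reference allele length ≤ tol and the longest
alternative ≥ 50; DEL when the shortest alternative ≤ tol and the
reference ≥ 50; otherwise SUB if any allele reaches 50; otherwise the
bubble is dropped as sub-SV-sized. `small_allele_tol = 5` reproduces
catalog conventions that admit a 1–5 bp residual allele on the "empty"
side; 0 is the strict default. Biallelic means exactly two traversals
(reference plus one alternative). NRUIs are the nodes of INS-type
bubbles containing no reference-derived node, filtered at strictly
\> 50 bp. The NRS filter is also strict `>` (configurable to `≥`); the
two length conventions in circulation differ at exactly the 50 bp
boundary, so both are exposed.

## Virtual SNPs and marker statistics

A deletion `[s, e]` (1-based inclusive) is array-genotypable when
`base(s) ≠ base(e+1)`; then `base(s)` is the reference allele and
`base(e+1)` the alternative. The opposite-strand confirmation compares
`base(e)` with `base(s−1)`. The two tests are mirror images: the forward
test of the reverse-complemented sequence with mirrored coordinates
equals the reverse test of the original (property-tested). Deletions
touching the sequence ends or with an ambiguity base at a tested
position are reported not-convertible with a reason; both flags are
reported and filtering is left to the caller, since a marker may pass
one strand only. Informativeness: He = 2pq, PIC = He − 2p²q², MAF =
min(p, q), with frequencies from observed allele counts over non-missing
calls. A marker is polymorphic when both alleles are observed at least
once in the full genotyped set; panel means are computed over polymorphic
markers only, with the monomorphic count reported separately.

## Population structure

PAV matrices are binary carriage indicators. Clustering uses Jaccard
distance — shared absences carry no information for presence data — and
complete linkage; both are configuration, not hard-coded. Samples are
sorted lexicographically before distance computation so the tree and the
flat labels at `k` are input-order invariant. PCA mean-imputes missing
dosages per marker, drops zero-variance markers (logged), centers and
scales to unit variance (so total variance equals the retained marker
count), and fixes component signs by making each component's dominant
loading positive.

## Mixed-model association

The model is `y = 1μ + xβ + u + e` with `u ~ N(0, G σ²_u)` and
`e ~ N(0, D σ²_e)`. **G** is VanRaden method 1 with observed allele
frequencies, `G = ZZ'/(2Σ p_j(1−p_j))`, after per-marker mean imputation
and removal of monomorphic markers. **D** is diagonal with `D_ii = 1/w_i`
where `w_i` is a per-animal accuracy weight; in this package weights are
treated as *relative* reliabilities with mean near 1 (an absolute
daughter-count scale would only rescale σ²_e, but it also makes the
per-animal residual negligible next to the polygenic term and thus the
ratio poorly identified — hence the relative convention, used by the
simulator default `w ~ U(0.5, 2)`).

REML estimates the single ratio λ = σ²_u/σ²_e on the null model after
whitening by `D^(−1/2)` and eigendecomposing the whitened GRM; the
1-D profile criterion is minimized over `log λ ∈ [−8, 8]` (Brent,
tolerance 1e-8). Estimates at a search bound, or on a profile whose
likelihood is flat to within 1e-4 of the bounds (e.g. G = I, where only
σ²_u + σ²_e is identified), are flagged. The scan holds (σ²_u, σ²_e)
fixed and computes, per marker, the GLS estimate with an intercept via
the same eigendecomposition — weighted inner products only, no
per-marker matrix inversion — and a Wald χ²₁ p-value; this route agrees
with explicit-inverse GLS to ~1e-13 relative. Monomorphic markers get
p = 1 and a flag. Genome-wide significance is Bonferroni α/m; the
somatic-cell trait transform SCS = 3 + log₂(SCC/100,000) is provided.

QTL grouping is iterative: the most significant unassigned significant
marker (ties: smaller p, then smaller position) becomes a peak, and
every significant marker on the same chromosome within the peak-centered
window (default 10 Mb total, i.e. ±5 Mb) whose squared Pearson
correlation of dosages with the peak exceeds 0.7 joins its region. The
window anchoring (peak-centered vs tiled) and both thresholds are
configuration; peak-centering is the default reading of a "10 Mb
window" rule. The output partitions the significant markers and each
region's peak is its most significant member.

## The simulator

The generator emulates the study design the pipeline targets: a
multi-breed panel of haploid assemblies over one linear reference.

* Reference: uniform-base DNA, default one 2 Mb chromosome (desk scale).
* SVs: default 120 non-overlapping sites with ≥ 200 bp gaps; the
  biallelic type mix (0.32 INS / 0.29 DEL / 0.39 SUB) and a 0.2
  multiallelic fraction follow the proportions of graph-based cattle SV
  catalogs; lengths mix point masses at 150 bp (0.35), 250 bp (0.25) and
  5.5 kb (0.05) — the transposable-element peaks — with a log-normal body
  (median 300 bp, σ = 1) clipped to [50, 8000].
* Breed structure: 14 breeds × 4 assemblies by default. Alt-allele
  frequencies follow a Balding–Nichols draw around a uniform ancestral
  frequency with divergence F (default 0.2); a configurable fraction of
  SVs (default 0.15) is breed-private with carrier frequency 0.5–0.9 in
  its breed. The `high_divergence_preset` (F = 0.5, half the SVs
  private, 200 SVs on 3 Mb) is the regime in which PAV clustering and
  PCA are expected to recover breeds exactly (ARI = 1); at the desk
  default, carriage separates breeds only partially, which is the
  realistic behavior the monotonicity property covers.
* Carriage is haploid per assembly (one allele per bubble, as for
  collapsed assemblies); every alt allele is guaranteed at least one
  carrier so the planted table is exactly the ideal call set. Haplotypes
  are the reference edited left-to-right by the carried alleles, and the
  emitted graph/path files reproduce them node-for-node (the
  concatenation oracle). A few uncarried "nested" nodes (default 5) are
  planted to exercise the nested-node filters.
* Diploid cohorts: breed-structured SNP/SV dosages in Hardy–Weinberg
  proportions within breed, and paternal half-sib families
  (`simulate_halfsib_genotypes`) for variance-component work — family
  blocks in G are what make σ²_u/σ²_e identifiable; unrelated HWE panels
  leave the ratio nearly flat and are used only for scan calibration,
  where that is harmless.
* Phenotypes: `y = 1μ + xβ + u + e` with `u = L z√σ²_u` (L a Cholesky
  factor of G with a minimal ridge), `e_i ~ N(0, σ²_e/w_i)`, σ²_u = h²,
  σ²_e = 1 − h² (total variance 1). The causal marker's β is sized to
  explain a given fraction (default 5%) of σ²_u + σ²_e.

What the generator does *not* emulate: sequencing or assembly error
(paths are complete and exact, so call recall/precision 1 reflects
algorithmic correctness, not robustness to noisy realignment),
overlapping or nested SVs (merged-bubble handling is exercised only by
unit fixtures), inversions as reconstructed sequence (orientation is
parsed but the generator emits "+" traversals; inverted alleles would
classify as substitutions), linkage disequilibrium along the chromosome
(markers are independent given breed, so LD-based QTL grouping is tested
with explicitly constructed LD blocks), and real trait architectures
(single causal variant plus a polygenic term).

## Problem sizes and numerics

The desk preset (2 Mb, 56 assemblies, 120 SVs, 2,000 SNPs) runs the full
pipeline in a few seconds; statistical checks use 20 replicate seeds at
n = 400–1,000 animals, chosen so the whole suite and the acceptance
script each complete in minutes on one CPU. The end-to-end cohort is
1,000 bulls (100 half-sib families), a scaled-down stand-in for real
breed panels of several thousand, large enough that a 5%-variance
deletion clears the Bonferroni threshold with high probability.
Numerical choices: eigenvalues of whitened GRMs are clipped at 0;
Cholesky factors add a 1e-8 ridge; REML uses `xatol = 1e-8` on log λ;
PCA sign-fixing uses the dominant loading; merge tie-breaks and allele
ordering are lexicographic so every stage is deterministic under a fixed
seed and independent of input order.

## Known limitations

* Bubble enumeration is path-driven: variation present in the graph but
  traversed by no sample (nested alleles) is invisible to calling, by
  design.
* Samples covering only one anchor of a merged bubble are genotyped
  missing even if their covered side matches the reference.
* The REML profile search is bounded at λ ∈ [e⁻⁸, e⁸]; heritabilities
  indistinguishable from 0 or 1 at the data's resolution are reported at
  the boundary with a flag rather than extrapolated.
* `group_qtl` computes r² from raw dosage correlation (mean-imputed),
  not haplotype-phased LD.
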