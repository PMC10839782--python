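# Methods

This note documents the statistical model behind `strpopgen`, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
data generator does and does not emulate.

## Allele model

An STR allele is modelled as its repeat region only: an ordered list of
motif blocks (motif of 2–6 bases, positive count) plus an optional trailing
partial unit shorter than the marker period. Flanking-region SNPs are out
of scope. The CE designation of a structure is the sum of block counts,
with a `.k` suffix when a k-base partial unit is present (the standard
microvariant convention: a 3-base remainder at a tetranucleotide marker
gives a `.3` label). Two resolutions coexist:

- **sequence level** — alleles compare equal by (marker, normalized block
  structure); the canonical text form is bracket notation with abutting
  blocks and the partial unit after a single space (`[TCTA]4[TCTG]6 TCA`).
  Parsing tolerates arbitrary whitespace between tokens.
- **length level** — alleles compare equal by (marker, CE designation).
  Collapsing is many-to-one and exact; every accessor can project a table
  to length level on the fly, so the two analysis levels are always
  computed from the same underlying calls.

Plain CE labels and bracket strings may be mixed within one column; a
plain label simply carries no sub-CE information and is its own sequence
identity.

## Direct counting and the forensic parameters

Frequencies are relative counts over typed gene copies only
(complete-case per locus): 2N copies at diploid loci, one per typed male
at haploid loci. The per-locus parameters are standard:

| quantity | formula | note |
|---|---|---|
| H_obs | het. individuals / typed individuals | |
| H_exp = GD | (g/(g−1))(1 − Σp²) | unbiased Nei estimator, g = gene copies; one code path for both names |
| PIC | 1 − Σp² − Σ_{i<j} 2p²_i p²_j | Botstein |
| PM | Σ (genotype sample frequency)² | over *observed* genotypes, not HWE-expected — the direct-counting convention; PD = 1 − PM exactly |
| PE | h²(1 − 2hH²), h = H_obs, H = 1 − h | trio-exclusion form; verified against two independent published (H_obs, PE) pairs before freezing |
| TPI | 1/(2(1 − H_obs)) | undefined at H_obs = 1 (raises) |

Combined powers multiply per-locus complements; the residuals
Π(1 − PE) and Π(1 − PD) reach magnitudes like 1e-60, so they are
accumulated as Σ log1p(−x) with `math.fsum` and exponentiated once. A
locus with PE or PD equal to 1 saturates the combination (residual 0).
Residuals are formatted `1-5.0779620E-21`-style for comparability with
published tables.

## Hardy–Weinberg exact test

The test conditions on the observed allele counts. The conditional
probability of a genotype array is proportional to 2^H / Π n_g! with H the
number of heterozygotes; the p-value is the total conditional probability
of arrays no more probable than the observed one.

- **Two alleles**: full enumeration over all heterozygote counts with the
  right margins and parity (exact, no randomness).
- **More alleles**: Monte-Carlo permutation of the flattened gene array —
  17,000 replicates by default, batched and vectorised (argsort of random
  keys, chunks of 2,000 for bounded memory), with the add-one estimator
  (1 + hits)/(1 + B), which keeps the result a valid p-value. The seed and
  replicate count are recorded in the result.
- Monomorphic locus: p = 1 by convention.
- Ties in the statistic are accepted within 1e-9 on the log scale.

Calibration is asserted in the acceptance tests: over 2,000 tables
simulated under HWE (100 diploids, 6 alleles, Dirichlet(1.5) frequencies,
1,000 permutations each), the rejection rate at α = 0.05 must sit inside
the 99% binomial interval around 0.05, and power must grow with the
inbreeding coefficient F. Bonferroni correction flags a locus only when
p < α/m over the m tested loci.

## Y haplotypes

A haplotype is the tuple of a male's calls over a locus panel; multi-copy
loci contribute sorted multisets, so copy order never matters, and a
copy-number variant simply yields a larger multiset. Males missing any
component are excluded per panel (not per locus): haplotypes must be
complete to compare; the exclusion count is reported. HMP = Σp², HD =
n(1−HMP)/(n−1), DC = distinct/n. The unique fraction is singletons over
*distinct* haplotypes. Per-locus haploid GD uses the same n/(n−1)
correction with the multiset as a compound allele; per-locus n is the
number of males typed at that locus. Kit comparison re-runs the haplotype
statistics on locus subsets over the same cohort.

## Population distances

**Fst** uses Weir & Cockerham's θ: per locus and allele the variance
components a (among populations), b (among individuals within populations)
and c (within individuals) are computed from sample sizes, allele
frequencies and heterozygote frequencies, and θ = Σa / Σ(a+b+c) over all
loci and alleles — the standard ratio-of-sums multi-locus combination.
When only frequency tables are available a Nei–Chesser corrected Gst is
used instead and the estimator name is recorded in the matrix metadata.

**Rst** treats alleles as integer repeat counts (stepwise-mutation logic):
a one-level AMOVA on the haploid counts yields σ²_among and σ²_within per
locus (MS differences scaled by the unequal-sample-size coefficient n′),
components are summed over loci, and Rst = σ²_a/(σ²_a+σ²_w). The ratio is
invariant under affine transforms of the counts (shifts cancel in squared
differences, scales cancel in the ratio), which the tests assert.
Microvariant labels (9.3) map to their integer part by default; a `skip`
mode excludes such loci instead. Multi-copy loci are excluded — there is
no single repeat count per sample — with a warning.

Negative point estimates of either statistic (expected when true
differentiation is ~0) are floored at 0 in the distance matrix, because
MDS and NJ require non-negative dissimilarities; the raw values are kept
in `DistanceMatrix.raw`.

## Structure analysis

**MDS** is classical/Torgerson scaling: B = −½ J D² J, eigendecomposition,
coordinates from the top eigenvectors scaled by √λ. Only positive
eigenvalues generate coordinates; requesting more dimensions than there
are positive eigenvalues truncates with a warning. Metric MDS was chosen
over non-metric because it is deterministic and exact on Euclidean input,
giving a testable contract (embedding distances reproduce the input to
1e-8 on planted configurations). The default output dimensionality is 2.

**Neighbour joining** is the Saitou–Nei agglomeration with the Q-matrix
criterion and the standard two-point branch-length formulas. All
tie-breaking is deterministic: among equal-Q pairs the lexicographically
smallest pair of clade labels (a clade is labelled by its smallest leaf)
is joined, and the final trifurcation's children are ordered by clade
label, so identical input always yields an identical tree. Negative branch
lengths are floored at 0 with the deficit moved to the sibling branch;
raw lengths are retained on the edges. On additive matrices NJ is exact:
tree path lengths equal the input to 1e-9, which the acceptance tests
verify on 100 random 4–10-taxon trees. Newick output carries branch
lengths at 6 decimals and quotes reserved characters. Both MDS and NJ are
implemented in-package because the contracts above (determinism, flooring
policy, eigenvalue reporting) are part of the interface; scikit-bio's
`pcoa` and `nj` serve as independent oracles in the test suite.

## Synthetic data generator

The generator produces data with the statistical *shape* of a
single-population MPS forensic study, with every generating parameter
known, so parameter-recovery and refinement properties can be asserted
exactly. Defaults (all overridable in `SimConfig`):

- **cohort**: 628 samples, 547 male / 81 female; Y markers generated for
  males only.
- **panel**: the named 52 autosomal + 81 Y markers (four multi-copy a/b
  loci); period 4 except the penta- and tri-nucleotide exceptions.
- **length-allele counts**: autosomal 6 + Binomial(19, 0.25) (range 6–25,
  mean ≈ 10.75, matching the low-skewed counts such panels report);
  Y single-copy 1 + Binomial(12, 0.4); multi-copy 8 + Binomial(6, 0.5);
  two Y loci (DYS502, DYS613) kept monomorphic, as real panels carry
  near-invariant loci. Allele frequencies are symmetric Dirichlet(1.5).
- **iso-length variants**: each length allele splits into 1–4 sequence
  variants with probabilities (0.60, 0.25, 0.10, 0.05), mean 1.6 — chosen
  so the sequence-level inventory is ≈1.6× the length-level one, the ratio
  such studies observe. Variant structures move j units from the primary
  motif block to a secondary block, so collapse is exact by construction.
  Sub-frequencies are Dirichlet shares of the parent mass with the last
  share taking the residual, making conservation exact to the last bit.
- **autosomal genotypes**: two independent draws (HWE) or, with
  inbreeding F, one duplicated draw with probability F, giving
  P(aa) = p² + Fp(1−p).
- **Y haplotypes**: a founder-lineage model — 400 founder haplotypes drawn
  locus-wise, each male copies a uniform founder, then every allele copy
  takes a ±1 single-step repeat mutation with probability 0.002.
  Independent loci would overstate haplotype diversity; the founder model
  induces the inter-locus dependence real patrilineages show. An
  independent-loci mode exists (`n_founders=None`).
- **divergence**: Balding–Nichols — per population and locus, frequencies
  drawn from Dirichlet(p_i(1−F_div)/F_div) around the ancestral vector,
  so F_div is the known Fst truth for recovery tests.

What the generator does **not** emulate: flanking-region variation,
genotyping error and allelic dropout, locus-specific mutation-rate
differences, linkage between autosomal loci, realistic Y haplogroup
structure, and allele-frequency correlation across neighbouring repeat
lengths. Passing tests therefore demonstrate correctness of the
*estimators and pipeline* under the stated model, not robustness to those
real-data complications.

## Problem sizes in the test and acceptance runs

The shared test fixture uses 240 samples; the refinement-monotonicity
check runs the full 628-sample panel once; HWE calibration uses 2,000
tables of 100 diploids; Fst recovery uses 50 replicates of 2×500 diploids
at 15 loci. These sizes give stable statistics (binomial 99% CI half-width
±0.0126 for the calibration; standard error ≈0.003 for mean θ) while the
whole suite runs in well under a minute.

## Known limitations

- PM from observed genotype frequencies makes PD sample-size dependent at
  small N (all-distinct genotypes give PM = 1/N).
- The frequency-only Fst fallback is a different estimator family from θ;
  matrices mixing the two should not be compared entry-wise (the statistic
  name is stored in metadata for this reason).
- Rst's integer-part convention for microvariants slightly compresses
  repeat-count variance at loci rich in partial repeats; use
  `microvariants="skip"` to drop such loci instead.
- The DYS389II label is stored as given, not net of DYS389I.
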