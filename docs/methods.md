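# Methods

This note documents the models, defaults and design choices behind each
analysis stage, what the synthetic-data generators do and do not emulate,
and the package's known limitations.

## Coordinates and inputs

All per-site results are keyed to a canonical 1-based residue numbering
anchored to a designated reference record of each alignment (for octopod
haemocyanin work, the full *Enteroctopus dofleini* sequence, UniProt
O61363; the analysed fragments of functional units f and g span positions
2306–2708 in that frame). Reference-gap columns carry no canonical number.
Record ids follow a `SpeciesCode_CloneId` convention (configurable regex);
climate of origin is an ordered factor coded polar = 0 < temperate = 1 <
subtropical = 2 < tropical = 3, so "warmer is larger" and a negative
correlation means the quantity decreases toward warm climates. PDB
structures are read first-model-only; alternate locations keep the
highest-occupancy conformer (ties favour altloc "A") and HETATM records are
excluded — a deterministic single-conformer view. Van der Waals radii are
fixed: C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å.

## Conservation (Jensen–Shannon divergence)

A column's amino-acid distribution `p_c` is compared with a background `q`
(BLOSUM62 marginal frequencies, hard-coded; they sum to 1 exactly) by the
base-2 Jensen–Shannon divergence, bounded in [0, 1], and down-weighted by
the gap fraction: `S(c) = (1 − g_c)·JSD(p_c, q)`. The windowed score mixes
each column with the mean of its neighbours up to `window_size` columns
each side (centre column excluded, window truncated at edges):
`W(i) = (1−λ)S(i) + λ·mean(S(j))`. Defaults `window_size = 3`,
`λ = 0.5` follow the scoring scheme's published defaults. Rows are
unweighted: clone redundancy is assumed to be handled upstream by sequence
selection; a weighting hook would be the natural extension. No pseudocounts
are added; `0·log 0 = 0` and all-gap columns score 0.

## Counting-based selection (SLAC-style)

*Ancestors.* Ancestral states are reconstructed at nucleotide (not codon)
granularity by per-column marginal maximum likelihood under HKY85 with
empirical base frequencies, branch lengths taken from the input tree, and a
transition/transversion ratio estimated by a moment method (observed
transition/transversion difference proportions over sequence pairs,
re-weighted by the base-frequency pairing terms; fallback κ = 2 when no
transversions are seen). Posterior ties are broken alphabetically
(A < C < G < T) and logged, making the reconstruction deterministic.
Reconstructing nucleotides rather than codons keeps the state space small
and matches the single-ancestor counting scheme; the cost is that an
inferred ancestral codon can occasionally be a stop, in which case the
affected branch/site change is left uncounted (warned).

*Counting.* For every branch and codon site, parent and child codons are
compared. Multi-nucleotide changes are scored by averaging synonymous and
nonsynonymous step counts over all minimal mutational paths that avoid stop
codons; if every path is blocked the branch/site is unresolved. Expected
proportions ES/EN are each parent codon's fraction of stop-free
single-nucleotide mutation targets that are synonymous/nonsynonymous
(universal genetic code only), averaged over branches weighted by branch
length; ES + EN = 1 at every resolvable site. Rates are
`dN = ON / (3·EN)`, `dS = OS / (3·ES)` (three nucleotide positions per
codon) and the reported per-site statistic is `(dN − dS) / T` with `T` the
total tree length.

*Test.* One-sided extended binomial tails:
`p_pos = P[X ≥ ON]` with `X ~ Binomial(n = ON + OS, p = EN)`, and the
mirror image for negative selection. Path averaging yields fractional
counts; the test rounds them half-even (the fractional values stay in the
output). Sites with no substitutions report p = 1 both ways. The discrete
tails make this test conservative — its realised type-I rate sits at or
below the nominal level.

## Likelihood companion (FEL-style)

Each site is fitted under a simplified MG94×HKY codon model on the 61
sense codons: single-nucleotide exchanges get rate
`κ^(ts) · π(target) · α` (synonymous) or `· β` (nonsynonymous), stop codons
are excluded, and the generator is scaled so α = β = 1 gives one expected
substitution per codon site per unit branch length at stationarity
(stationary codon frequencies ∝ products of the nucleotide frequencies).
The alternative fits (α, β) by L-BFGS-B in log space (bounds 10⁻⁴–50,
ftol 10⁻¹⁰); the null constrains α = β (bounded scalar minimisation);
p comes from χ²(1) on the likelihood ratio. Invariant sites short-circuit
to p = 1. Because the LRT is evaluated per site on tens of substitutions,
the χ²(1) reference shows mild Bartlett-type inflation at low divergence
(mean LRT ≈ 1.25 at ~7 substitutions/site, converging to 1 as information
grows); this is a property of the published method, documented rather than
corrected.

## Multi-test consensus

MEME, FUBAR, EF, PRIME and TreeSAAP are never computed internally — these
tests are typically run on external web services — and enter through a
generic per-site result table (site, test, direction, statistic kind,
value). Default thresholds: p ≤ 0.10 for SLAC, FEL, MEME; p ≤ 0.05 for
PRIME (a 0.10 variant is sometimes quoted for it; the stricter value is the
default and the threshold is configurable); posterior probability ≥ 0.90 for
FUBAR; Bayes factor ≥ 0.50 for EF (unusually permissive, implemented as
printed); TreeSAAP rows carry the significance field of magnitude-≥ 6
property categories and count when ≤ 0.001. A site is consensus-positive
when ≥ `min_tests` (default 3) tests are significant in the positive
direction; missing tests count as non-significant; duplicate (site, test)
rows are a hard error.

## Surface exposure

SASA uses the Shrake–Rupley construction with a deterministic golden-angle
spiral point set (default 960 points/atom, probe 1.4 Å): a sphere point on
the expanded radius `r_vdw + probe` is accessible iff it lies outside every
neighbour's expanded sphere; the atom's area is the accessible fraction of
`4π(r+probe)²`. No RNG is involved, so areas are bit-stable. The point-set
resolution bounds the accuracy: isolated-sphere error < 2% at 960 points;
tolerances used for rotation-invariance (0.5%) and convergence (1%) checks
are honoured at 7680 and 1920→3840 points respectively, because the most
occluded atoms in test fixtures expose only ~25 Å².

Residues are classed by the ratio of residue SASA to the Miller et al.
(1987) standard-state reference areas: ratio > 0.5 exposed, < 0.2 buried,
else intermediate — the three-way in/out/intermediate scheme of
GETAREA-style tools. The ratio deliberately uses the whole residue rather
than the side chain alone: side-chain reference areas are undefined for
glycine, and on the structures tested the two ratios order residues the
same way. Side-chain SASA is still reported per residue.

Alignment→structure mapping is a global pairwise alignment (BLOSUM62, gap
open −11, extend −1) between the fragment's ungapped reference sequence
and the chain sequence; aligned non-gap pairs define a bijective residue
map, and an identity below a configurable floor (default 0.3, permissive
enough for paralog-level homology such as mapping FU f sites onto an FU g
structure) is rejected as a wrong-structure error. Numbering is always
bridged through this mapping, never via hard-coded offsets. The 4.0 Å
salt-bridge/hydrogen-bond criterion is exposed as a constant for
annotation.

## Charges and titration

Side-chain charges follow Henderson–Hasselbalch with a documented default
pKa table: Asp 3.65, Glu 4.25, Cys 8.5, Tyr 10.1 (acidic); His 6.5,
Lys 10.8, Arg 12.5 (basic). The table is configurable and every reported
charge is conditional on it. Termini are not titrated — the analysed
regions are internal fragments. Net charge over a position subset is the
sum of fractional charges (strictly decreasing in pH when any titratable
residue is present; saturating at +#basic / −#acidic); an integer-charge
mode (±1 for Asp/Glu/Lys/Arg, +1 for His) is provided because published
charge tallies sometimes count integers — which convention a given source
used is often unstated, so both are reported by the census. His is counted
among the positively charged residues in censuses even though its
fractional charge near pH 7.3 is small (~+0.15); count and fractional
charge are reported separately. The alpha-stat model is the linear
imidazole buffer line `pH(T) = 7.27 − 0.0153·(T − 10 °C)` (reference:
venous pH 7.27 at 10 °C); temperatures outside −2–35 °C warn.

## Climate statistics

The composition matrix has one row per sequence record (counts of each
polar residue type over the surface set, plus net charge). PCA runs on the
covariance matrix (variables share units; correlation-matrix scaling is
optional and refuses zero-variance columns), with a deterministic sign
convention — each component's largest-magnitude loading is positive.
Kendall tau-b with tie-corrected variance and a two-sided normal
approximation measures association with the climate ordinal; all-tied
inputs are flagged undefined rather than returned as numbers.
Record-level rows (multiple clones per species) are the default to match
how such datasets are usually plotted, but clones are pseudo-replicates:
with near-identical clones the record-level test is anticonservative
(measured ~13–16% null rejections at α = 0.05 with 2 clones/species), so
calibration experiments and any inference should use the species-mean
aggregation, which is calibrated (~95% non-significant under a null
gradient). This caveat applies equally to clone-level correlations on real
data. No phylogenetic correction (PGLS/independent contrasts) is applied —
a known limitation: climate is phylogenetically clustered in octopods, and
the correlations are descriptive, not phylogenetically independent.

## Synthetic data

*Codon alignments.* Evolution runs on a symmetric binary tree (default 16
tips, branch length 0.25 — total length 7.5 expected substitutions per
codon site, putting typical sites in the several-to-tens substitution range
seen in multi-species coding alignments) under the same MG94×HKY generator
the FEL fit uses, with per-site ω multiplying the nonsynonymous rates.
Branches are simulated exactly (Gillespie per site per branch) rather than
via matrix exponentials, which excludes stop codons exactly and needs no
linear algebra; root codons are drawn from the stationary distribution.
Defaults emulate a mostly purifying gene: 180 sites at ω = 0.2, 20 at
ω = 5. What this does not emulate: indels (the DPEKG indel is data, not
simulated), rate variation beyond the two-class ω mix, recombination, and
real base composition.

*Climate gradients.* 7 species per climate class, 2 clones each, a
65-position surface set within a 100-residue fragment. Twenty gradient
positions hold Lys or Glu; each species' Lys count targets `m·p_class`
with N(0, 0.5) between-species jitter, where `p_class` falls by
`δ/(2m)` per climate step so the expected net charge drops δ (default 1.5
elementary charges) per step toward warmer climates — the Glu↔Lys
substitution axis observed in cold-adapted octopods. The jitter scale is
chosen so the prescribed effect size dominates within-class spread (charge
sd ≈ 1 vs a 1.5 step), giving the null/power behaviour the calibration
experiments assert: a δ = 0 gradient is non-significant in ≥ 90% of seeded
datasets and δ = 1.5 is recovered (negative tau, p < 0.01) in ≥ 95%, both
at species level. Clones are near-copies (per-position flip probability
0.02). Real clone/allele/isoform structure is richer than this; in
particular the generator has a single isoform, so it cannot reproduce
isoform-split correlation reversals.

*Structures.* Toy kinds with analytic or known surface behaviour: a single
carbon (closed-form sphere area), a two-carbon dimer (spherical-cap
formula), a shell that fully encloses a centre atom (SASA exactly 0), and
a tight single-atom-per-residue helix giving mixed exposure classes.

*Reproducibility.* One global seed fans out to per-component streams via
`numpy.random.SeedSequence.spawn`; same (config, seed) gives byte-identical
outputs, and the fixture-bundle writer records a manifest of summary values
recomputed by the tests.

## Problem sizes

Test and acceptance runs use 16-tip trees, 200-site calibration alignments,
100-seed climate calibrations, and ≤ 7680-point sphere samplings — sizes at
which every oracle comparison and calibration experiment completes in
seconds on one CPU while keeping binomial confidence intervals tight enough
to be meaningful.

## Pipeline behaviour

Stages run in dependency order from one TOML config; a stage with missing
inputs is skipped with an explicit reason, a failed stage marks dependants
skipped and the run failed (exit code 3; config validation errors exit 2).
Reports carry a provenance block (package version, input hashes, stage
statuses) and are byte-identical across reruns of the same config and
inputs.
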