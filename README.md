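# hemocharge

Molecular-evolution and structural-biochemistry analysis of octopod
haemocyanin — the copper-based oxygen transporter that lets octopuses live
everywhere from Antarctic shelves to tropical reefs. The package asks how
natural selection reshaped this protein across climates, and answers with a
chain of five analyses over coding alignments, a phylogeny, a crystal
structure and species metadata:

1. **Conservation** — per-column Jensen–Shannon divergence (JSD) of the
   protein alignment against the BLOSUM62 amino-acid background, with a
   neighbour window: `S(c) = (1 − g_c) · JSD(p_c, q)`,
   `W(i) = (1−λ)S(i) + λ·mean{S(j): 0<|i−j|≤w}`.
2. **Selection** — counting-based per-site dN − dS (SLAC-style): marginal-ML
   ancestral reconstruction under HKY85, branch-by-branch tallies of
   observed synonymous/nonsynonymous changes with stop-free minimal-path
   averaging, extended-binomial one-sided tests, a per-site likelihood-ratio
   companion (FEL-style, simplified MG94×HKY, χ²(1)), and a consensus caller
   that declares a site positively selected when ≥ 3 of up to 7 tests
   (SLAC, FEL, MEME, FUBAR, EF, PRIME, TreeSAAP — the last five read from
   external result tables) are individually significant.
3. **Surface** — Shrake–Rupley solvent-accessible surface area with a
   deterministic golden-spiral point set (probe 1.4 Å), three-way
   exposed/intermediate/buried classes, alignment↔structure residue mapping
   by pairwise alignment, and minimum-distance queries between atom
   selections.
4. **Charge** — Henderson–Hasselbalch fractional charges
   (`+1/(1+10^(pH−pKa))` basic, `−1/(1+10^(pKa−pH))` acidic), net surface
   charge at a reference pH, titration ("buffer line") curves, polar-residue
   censuses, and the alpha-stat haemolymph pH model
   `pH(T) = 7.27 − 0.0153·(T − 10 °C)`.
5. **Climate** — composition PCA and Kendall tau-b correlation of net
   surface charge against the ordinal climate of origin
   (polar < temperate < subtropical < tropical).

A first-class synthetic-data module generates every input — codon
alignments evolved on a tree with site-specific dN/dS (exact Gillespie
simulation, no stop codons), climate-stratified surface-charge gradients
built from Glu↔Lys composition shifts, and toy structures with closed-form
surface areas — so the whole chain runs and is tested without downloads.

## Worked example

```python
from hemocharge import simulate as sim
from hemocharge.selection import slac_analysis
from hemocharge.charge import polar_census, ph_alpha_stat
from hemocharge.climate import kendall_climate_correlation

# a 16-taxon coding gene: 90 purifying sites (omega 0.2), 10 positive (omega 5)
cfg = sim.SimulationConfig(n_tips=16, branch_length=0.25,
                           site_omegas=(0.2,) * 90 + (5.0,) * 10, seed=7)
codon, tree, omegas = sim.simulate_codon_alignment(cfg)
counts, tests = slac_analysis(codon, tree)
print("tree length:", round(tree.total_length, 2))
print("sites flagged for positive selection:",
      tests[tests.p_positive <= 0.10].site.tolist())

# climate-stratified surface charges: 28 species, 2 clones each
aln, species, surface, _ = sim.simulate_climate_dataset(sim.ClimateGradientConfig(seed=7))
census = polar_census(aln, surface, reference_ph=7.27)
df = census.table
df["ordinal"] = [species.ordinal_of(s) for s in df.species_code]
sp = df.groupby("species_code").agg(net_charge=("net_charge", "mean"),
                                    ordinal=("ordinal", "first"))
r = kendall_climate_correlation(sp.net_charge, sp.ordinal)
print(f"net surface charge vs climate: tau_b = {r.tau_b:.3f}, p = {r.p_value:.2e}, n = {r.n}")
print(f"haemolymph pH predicted at 0 C: {ph_alpha_stat(0.0):.3f}")
```

prints

```
tree length: 7.5
sites flagged for positive selection: [92, 93, 95, 96]
net surface charge vs climate: tau_b = -0.606, p = 4.77e-05, n = 28
haemolymph pH predicted at 0 C: 7.423
```

The counting test recovers a subset of the ten truly positive sites (91–100)
at its p ≤ 0.10 threshold with no false positives among the purifying sites;
the synthetic climate gradient — expected net charge dropping 1.5 elementary
charges per step toward warmer climates — comes back as a strong negative
tau-b; and the alpha-stat line reproduces the venous pH rise expected when
an ectotherm cools from 10 °C to 0 °C.

## Command line

`hemocharge` exposes each stage (`validate`, `conserve`, `select`,
`surface`, `charge`, `simulate`) plus `run --config analysis.toml`, which
executes all stages in dependency order and writes a joined per-site table,
a per-record census, correlation/PCA summaries and a provenance block.

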