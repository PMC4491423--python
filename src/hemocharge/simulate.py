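"""Synthetic inputs for every pipeline stage.

Three generators, all bit-reproducible from (config, seed):

* codon alignments evolved on a tree under a simplified MG94xHKY process
  with site-specific omega (dN/dS) targets, simulated exactly with a
  per-branch Gillespie algorithm that forbids stop codons — a stand-in for
  the study's haemocyanin coding alignments (mostly purifying sites, a
  minority positively selected);
* climate-stratified protein alignments whose surface residues carry a
  configurable net-charge gradient across the four ordinal climate classes
  (Glu<->Lys swaps, the substitution axis the study observed), with
  near-copy clones per species — a stand-in for the species/charge dataset;
* toy structures (single atom, dimer, enclosing shell, helix) with known
  analytic surface areas for exercising the SASA machinery.

One global seed fans out to per-component streams through
``numpy.random.SeedSequence.spawn``, so each stage is reproducible on its
own.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import charge as charge_mod
from .genetics import CODON_INDEX, GENETIC_CODE, SENSE_CODONS, translate_codon
from .io import (
    AlignmentRecord,
    MultipleAlignment,
    PhyloTree,
    ProteinStructure,
    Residue,
    Atom,
    SpeciesTable,
    ExternalTestTable,
    CLIMATE_ORDER,
    CLIMATE_ORDINAL,
    write_fasta_alignment,
    write_newick,
    write_pdb,
    write_species_table,
    write_test_table,
)
from .selection import CodonAlignment, _CodonModel

VDW_CARBON = 1.70


def symmetric_tree(n_tips: int, branch_length: float) -> PhyloTree:
    """Balanced binary tree with equal branch lengths; n_tips must be a
    power of two."""
    if n_tips < 2 or (n_tips & (n_tips - 1)) != 0:
        raise ValueError("n_tips must be a power of two >= 2")

    def newick(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"t{lo + 1}:{branch_length}"
        mid = (lo + hi) // 2
        return f"({newick(lo, mid)},{newick(mid, hi)}):{branch_length}"

    mid = n_tips // 2
    text = f"({newick(0, mid)},{newick(mid, n_tips)});"
    tree = dendropy.Tree.get(data=text, schema="newick")
    return PhyloTree(tree)


@dataclass
class SimulationConfig:
    """Codon-alignment simulation settings.

    ``site_omegas`` is one omega per codon site; defaults emulate a mostly
    purifying gene with a minority of positively selected sites (180 sites
    at omega 0.2, 20 at omega 5).
    """

    n_tips: int = 16
    branch_length: float = 0.25
    site_omegas: tuple[float, ...] = (0.2,) * 180 + (5.0,) * 20
    kappa: float = 2.0
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.site_omegas):
            raise ValueError("site omegas must be >= 0")
        if self.branch_length < 0:
            raise ValueError("branch length must be >= 0")
        if abs(sum(self.base_frequencies) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")


def _gillespie_branch(
    rng: np.random.Generator,
    model: _CodonModel,
    codon_idx: int,
    omega: float,
    t: float,
) -> int:
    """Evolve one codon along one branch; returns the end-state index."""
    state = codon_idx
    elapsed = 0.0
    while True:
        rates = model.syn[state] + omega * model.nonsyn[state]
        total = rates.sum()
        if total <= 0:
            return state
        elapsed += rng.exponential(1.0 / total)
        if elapsed >= t:
            return state
        state = int(rng.choice(len(rates), p=rates / total))


def simulate_codon_alignment(
    config: SimulationConfig,
) -> tuple[CodonAlignment, PhyloTree, np.ndarray]:
    """Simulate a stop-free codon alignment on a symmetric tree.

    Returns (codon alignment, tree, per-site true omega array). The root
    codon of each site is drawn from the model's stationary codon
    frequencies; evolution along each branch is an exact continuous-time
    simulation whose nonsynonymous rate is scaled by the site's omega and
    whose state space excludes stop codons.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    tree = symmetric_tree(config.n_tips, config.branch_length)
    model = _CodonModel(config.kappa, np.asarray(config.base_frequencies))
    n_sites = len(config.site_omegas)
    # root draw
    root_states = rng.choice(len(SENSE_CODONS), size=n_sites, p=model.pi)
    node_states: dict[int, np.ndarray] = {id(tree.tree.seed_node): root_states}
    for node in tree.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        t = node.edge.length or 0.0
        parent_states = node_states[id(parent)]
        child = np.empty(n_sites, dtype=int)
        for site in range(n_sites):
            child[site] = _gillespie_branch(
                rng, model, int(parent_states[site]), config.site_omegas[site], t
            )
        node_states[id(node)] = child
    records = []
    for leaf in tree.tree.leaf_node_iter():
        states = node_states[id(leaf)]
        seq = "".join(SENSE_CODONS[s] for s in states)
        label = leaf.taxon.label
        records.append(AlignmentRecord(label, label, "", seq))
    aln = MultipleAlignment(records=records, alphabet="nucleotide")
    return CodonAlignment(aln), tree, np.asarray(config.site_omegas)


def translate_alignment(codon_aln: CodonAlignment, canonical_start: int = 1) -> MultipleAlignment:
    """Protein alignment from an in-frame codon alignment (gap codons -> '-')."""
    records = []
    for rec in codon_aln.alignment.records:
        aas = []
        for site in range(codon_aln.codon_count):
            codon = rec.residues[3 * site : 3 * site + 3]
            if "-" in codon or "." in codon:
                aas.append("-")
            else:
                aa = translate_codon(codon)
                aas.append(aa if aa != "*" else "X")
        records.append(AlignmentRecord(rec.id, rec.species_code, rec.clone_id, "".join(aas)))
    return MultipleAlignment(records=records, alphabet="protein",
                             canonical_start=canonical_start)


@dataclass
class ClimateGradientConfig:
    """Climate-gradient protein dataset settings.

    Defaults mirror the study's footprint: 7 species per climate class
    (28 species total), 2 clones each, a 65-position surface set within a
    100-residue fragment, and an expected net-charge drop of
    ``delta`` = 1.5 elementary charges per step toward warmer climates,
    produced by Lys<->Glu composition shifts at 20 gradient positions.
    """

    species_per_class: int = 7
    clones_per_species: int = 2
    sequence_length: int = 100
    n_surface: int = 65
    n_gradient: int = 20
    delta: float = 1.5
    base_lys_fraction: float = 0.75
    species_noise_sd: float = 0.5
    clone_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")
        if self.n_gradient > self.n_surface or self.n_surface > self.sequence_length:
            raise ValueError("need n_gradient <= n_surface <= sequence_length")
        # the Lys probability must stay in [0,1] across all four climate steps
        if abs(self.delta) * 3 / (2 * self.n_gradient) > 1.0:
            raise ValueError("delta too large for the number of gradient positions")


# template residues for non-gradient surface (polar, charge-neutral mix) and
# for the buried remainder (hydrophobic)
_NEUTRAL_SURFACE = "STNQSTNQH"
_BURIED = "AVLIFMGW"


def simulate_climate_dataset(
    config: ClimateGradientConfig,
) -> tuple[MultipleAlignment, SpeciesTable, list[int], pd.DataFrame]:
    """Generate the climate-stratified protein dataset.

    Returns (protein alignment, species table, surface position list,
    truth table). The truth table carries, per record, the climate ordinal,
    the expected net charge of its gradient positions and the realised
    Lys/Glu counts from the generator's own bookkeeping.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    L = config.sequence_length
    surface_positions = list(range(1, config.n_surface + 1))  # canonical, 1-based
    gradient_positions = surface_positions[: config.n_gradient]
    neutral_positions = surface_positions[config.n_gradient :]

    # per-climate Lys probability at gradient positions: each Lys->Glu swap
    # moves the charge by ~2, so a delta drop per step needs delta/2 expected
    # swaps, i.e. a delta/(2*m) probability shift per step
    p_shift = config.delta / (2 * config.n_gradient)

    template = list(
        (_NEUTRAL_SURFACE * ((len(neutral_positions) // len(_NEUTRAL_SURFACE)) + 1))[
            : len(neutral_positions)
        ]
    )
    buried_template = (_BURIED * ((L // len(_BURIED)) + 1))[config.n_surface : L]

    species_rows = []
    records = []
    truth_rows = []
    code_index = 0
    for climate in CLIMATE_ORDER:
        ordinal = CLIMATE_ORDINAL[climate]
        p_lys = config.base_lys_fraction - p_shift * ordinal
        p_lys = float(np.clip(p_lys, 0.0, 1.0))
        for s in range(config.species_per_class):
            code = f"{climate[0].upper()}{code_index:02d}"
            code_index += 1
            species_rows.append(
                {
                    "species_code": code,
                    "species": f"Synthoctopus {climate}_{s + 1}",
                    "family": f"{climate.capitalize()}idae",
                    "climate": climate,
                }
            )
            # species-level draw: Lys count targets m*p_lys with small
            # between-species jitter (sd in residue-count units), so the
            # class gradient dominates within-class spread; clones are
            # noisy near-copies
            m = config.n_gradient
            n_lys = int(np.clip(
                round(m * p_lys + rng.normal(0.0, config.species_noise_sd)), 0, m
            ))
            base_gradient = np.full(m, "E", dtype="<U1")
            base_gradient[rng.permutation(m)[:n_lys]] = "K"
            for clone in range(config.clones_per_species):
                gradient = base_gradient.copy()
                flip = rng.random(config.n_gradient) < config.clone_noise
                gradient[flip] = np.where(gradient[flip] == "K", "E", "K")
                seq = np.empty(L, dtype="<U1")
                seq[[p - 1 for p in gradient_positions]] = gradient
                seq[[p - 1 for p in neutral_positions]] = template
                seq[config.n_surface :] = list(buried_template)
                seq_str = "".join(seq)
                rec_id = f"{code}_c{clone + 1}"
                records.append(AlignmentRecord(rec_id, code, f"c{clone + 1}", seq_str))
                n_k = int((gradient == "K").sum())
                n_e = int((gradient == "E").sum())
                truth_rows.append(
                    {
                        "record_id": rec_id,
                        "species_code": code,
                        "climate": climate,
                        "climate_ordinal": ordinal,
                        "expected_gradient_charge": config.n_gradient * (2 * p_lys - 1),
                        "n_K_gradient": n_k,
                        "n_E_gradient": n_e,
                    }
                )
    aln = MultipleAlignment(records=records, alphabet="protein")
    species_df = pd.DataFrame(species_rows)
    species_df["climate_ordinal"] = species_df.climate.map(CLIMATE_ORDINAL)
    return aln, SpeciesTable(species_df), surface_positions, pd.DataFrame(truth_rows)


def generate_toy_structure(kind: str, **params) -> ProteinStructure:
    """Deterministic toy structures with known/checkable surface areas.

    kinds: ``single_atom`` (one carbon; SASA is the closed-form sphere
    area), ``dimer`` (two carbons at ``separation`` Å; analytic
    spherical-cap area), ``shell`` (a centre atom completely enclosed by a
    spherical shell of atoms; centre SASA 0), ``helix`` (``n_residues``
    single-carbon alanines on a tight helix; mixed exposure classes).
    """
    from .surface import golden_spiral_points

    def carbon(name: str, xyz) -> Atom:
        return Atom(name, "C", float(xyz[0]), float(xyz[1]), float(xyz[2]), VDW_CARBON)

    if kind == "single_atom":
        return ProteinStructure([Residue("A", 1, "ALA", [carbon("CA", (0, 0, 0))])])
    if kind == "dimer":
        d = float(params.get("separation", 2.0))
        return ProteinStructure(
            [
                Residue("A", 1, "ALA", [carbon("CA", (0, 0, 0))]),
                Residue("A", 2, "ALA", [carbon("CA", (d, 0, 0))]),
            ]
        )
    if kind == "shell":
        n_shell = int(params.get("n_shell", 80))
        radius = float(params.get("radius", 4.0))
        atoms = [carbon("CA", (0, 0, 0))]
        shell_pts = radius * golden_spiral_points(n_shell)
        residues = [Residue("A", 1, "ALA", atoms)]
        shell_atoms = [carbon(f"C{i}", p) for i, p in enumerate(shell_pts)]
        residues.append(Residue("A", 2, "GLY", shell_atoms))
        return ProteinStructure(residues)
    if kind == "helix":
        n = int(params.get("n_residues", 12))
        radius = float(params.get("radius", 1.2))
        rise = float(params.get("rise", 0.9))
        turn = np.deg2rad(float(params.get("turn_deg", 100.0)))
        residues = []
        for i in range(n):
            x = radius * np.cos(i * turn)
            y = radius * np.sin(i * turn)
            z = i * rise
            residues.append(Residue("A", i + 1, "ALA", [carbon("CA", (x, y, z))]))
        return ProteinStructure(residues)
    raise ValueError(f"unknown toy structure kind {kind!r}")


def isolated_sphere_sasa(radius: float, probe: float = 1.4) -> float:
    """Closed-form SASA of an isolated atom."""
    return 4 * np.pi * (radius + probe) ** 2


def dimer_analytic_sasa(radius: float, separation: float, probe: float = 1.4) -> float:
    """Closed-form SASA of one atom of an identical-pair dimer.

    Each expanded sphere (R = radius + probe) loses a spherical cap of
    height h = R - d/2 when the centres are d < 2R apart:
    area = 4*pi*R^2 - 2*pi*R*h.
    """
    R = radius + probe
    if separation >= 2 * R:
        return 4 * np.pi * R**2
    h = R - separation / 2
    return 4 * np.pi * R**2 - 2 * np.pi * R * h


def default_external_tables(sites: list[int], positive_sites: list[int]) -> ExternalTestTable:
    """A constructed external-test table: MEME/FUBAR/EF significant at the
    designated positive sites, non-significant elsewhere."""
    rows = []
    for site in sites:
        hot = site in positive_sites
        rows.append({"site": site, "test": "MEME", "direction": "positive",
                     "kind": "p_value", "value": 0.01 if hot else 0.8})
        rows.append({"site": site, "test": "FUBAR", "direction": "positive",
                     "kind": "posterior_probability", "value": 0.97 if hot else 0.2})
        rows.append({"site": site, "test": "EF", "direction": "positive",
                     "kind": "bayes_factor", "value": 1.5 if hot else 0.1})
    return ExternalTestTable(pd.DataFrame(rows))


def make_fixture_bundle(out_dir: str | Path, seed: int = 0) -> dict:
    """Write a complete, self-consistent fixture set to ``out_dir``.

    Files: codon_alignment.fasta + tree.nwk (selection stage),
    protein_alignment.fasta (conservation), climate_alignment.fasta +
    species.tsv (charge/climate stages), toy.pdb (surface stage),
    external_tests.tsv (consensus), and manifest.json recording the seed
    and summary values computed from the generated data. Returns the
    manifest. Same seed -> byte-identical bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(seed).spawn(2)

    sim_cfg = SimulationConfig(
        n_tips=8, branch_length=0.2,
        site_omegas=(0.2,) * 40 + (5.0,) * 5,
        seed=int(streams[0].generate_state(1)[0] % (2**31)),
    )
    codon_aln, tree, omegas = simulate_codon_alignment(sim_cfg)
    write_fasta_alignment(codon_aln.alignment, out / "codon_alignment.fasta")
    write_newick(tree, out / "tree.nwk")
    protein = translate_alignment(codon_aln)
    write_fasta_alignment(protein, out / "protein_alignment.fasta")

    climate_cfg = ClimateGradientConfig(seed=int(streams[1].generate_state(1)[0] % (2**31)))
    climate_aln, species, surface_positions, truth = simulate_climate_dataset(climate_cfg)
    write_fasta_alignment(climate_aln, out / "climate_alignment.fasta")
    write_species_table(species, out / "species.tsv")
    truth.to_csv(out / "climate_truth.tsv", sep="\t", index=False)

    structure = generate_toy_structure("helix", n_residues=12)
    write_pdb(structure, out / "toy.pdb")

    sites = list(range(1, codon_aln.codon_count + 1))
    positive = [s for s, w in zip(sites, omegas) if w > 1]
    tests = default_external_tables(sites, positive)
    write_test_table(tests, out / "external_tests.tsv")

    from .conservation import conservation_profile

    profile = conservation_profile(protein)
    manifest = {
        "seed": seed,
        "codon_sites": codon_aln.codon_count,
        "n_codon_records": len(codon_aln.alignment.records),
        "total_tree_length": round(tree.total_length, 10),
        "true_positive_sites": positive,
        "surface_positions": surface_positions,
        "mean_jsd": round(float(np.mean(profile.jsd)), 10),
        "n_climate_records": len(climate_aln.records),
        "files": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def bundle_checksum(out_dir: str | Path) -> str:
    """SHA256 over the bundle's files (sorted); used to assert determinism."""
    h = hashlib.sha256()
    for path in sorted(Path(out_dir).iterdir()):
        h.update(path.name.encode())
        h.update(path.read_bytes())
    return h.hexdigest()
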