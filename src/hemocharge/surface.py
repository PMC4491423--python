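"""Solvent-accessible surface area, exposure classes, structure mapping and
distance queries.

SASA uses the Shrake–Rupley rolling-probe construction with a deterministic
golden-spiral point set on each atom's expanded sphere (radius r_vdw +
probe, probe default 1.4 Å — a water molecule). A point is accessible when
it lies outside every neighbouring atom's expanded sphere; the atom's SASA
is 4*pi*(r+probe)^2 times the accessible fraction. No randomness is
involved, so areas are bit-stable across runs.

Residues are classified exposed / intermediate / buried by the ratio of
their SASA to a random-coil reference area (ratio > 0.5 exposed,
< 0.2 buried), mirroring the three-way in/out/intermediate scheme of
GETAREA-style tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io import MultipleAlignment, ProteinStructure

#: Standard-state (random coil) residue areas in Å², Miller et al. (1987).
REFERENCE_AREAS = {
    "ALA": 113.0, "ARG": 241.0, "ASN": 158.0, "ASP": 151.0, "CYS": 140.0,
    "GLN": 189.0, "GLU": 183.0, "GLY": 85.0, "HIS": 194.0, "ILE": 182.0,
    "LEU": 180.0, "LYS": 211.0, "MET": 204.0, "PHE": 218.0, "PRO": 143.0,
    "SER": 122.0, "THR": 146.0, "TRP": 259.0, "TYR": 229.0, "VAL": 160.0,
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: Distance (Å) at or below which weak hydrogen bonds / salt bridges form.
SALT_BRIDGE_CUTOFF = 4.0


def golden_spiral_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points via the golden-angle spiral."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley_sasa(
    structure: ProteinStructure, probe_radius: float = 1.4, n_points: int = 960
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-atom SASA (Å²) and a per-residue summary table.

    Returns (atom_areas, residue_table) where the table has columns chain,
    residue_number, residue_name, sasa, sidechain_sasa.
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable sphere sampling")
    atoms = structure.atoms
    if not atoms:
        raise ValueError("structure has no atoms")
    coords = np.array([a.coord for a in atoms])
    radii = np.array([a.radius for a in atoms]) + probe_radius
    sphere = golden_spiral_points(n_points)
    n = len(atoms)
    areas = np.zeros(n)
    # neighbour lists by pairwise cutoff keeps the inner loop small
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    for i in range(n):
        cutoff2 = (radii[i] + radii.max()) ** 2
        neigh = [j for j in range(n) if j != i and d2[i, j] < cutoff2]
        pts = coords[i] + radii[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            dj = ((pts - coords[j]) ** 2).sum(-1)
            accessible &= dj > radii[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4 * np.pi * radii[i] ** 2 * accessible.mean()
    rows = []
    idx = 0
    for res in structure.residues:
        res_area = side_area = 0.0
        for atom in res.atoms:
            res_area += areas[idx]
            if atom.name not in BACKBONE_ATOMS:
                side_area += areas[idx]
            idx += 1
        rows.append(
            {
                "chain": res.chain,
                "residue_number": res.number,
                "residue_name": res.name,
                "sasa": res_area,
                "sidechain_sasa": side_area,
            }
        )
    return areas, pd.DataFrame(rows)


@dataclass
class ExposureProfile:
    """Per-residue SASA, reference-area ratio and exposure class."""

    table: pd.DataFrame  # chain, residue_number, residue_name, sasa,
    #                      sidechain_sasa, ratio, exposure


def classify_exposure(
    residue_table: pd.DataFrame,
    exposed_threshold: float = 0.5,
    buried_threshold: float = 0.2,
) -> ExposureProfile:
    """Three-way exposure classification from the SASA/reference ratio."""
    ratios, classes = [], []
    for _, r in residue_table.iterrows():
        ref = REFERENCE_AREAS.get(r.residue_name.upper())
        if ref is None:
            raise ValueError(f"no reference area for residue type {r.residue_name!r}")
        ratio = r.sasa / ref
        if ratio > exposed_threshold:
            cls = "exposed"
        elif ratio < buried_threshold:
            cls = "buried"
        else:
            cls = "intermediate"
        ratios.append(ratio)
        classes.append(cls)
    out = residue_table.copy()
    out["ratio"] = ratios
    out["exposure"] = classes
    return ExposureProfile(out)


def exposure_profile(
    structure: ProteinStructure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    exposed_threshold: float = 0.5,
    buried_threshold: float = 0.2,
) -> ExposureProfile:
    """SASA + classification in one call."""
    _, table = shrake_rupley_sasa(structure, probe_radius, n_points)
    return classify_exposure(table, exposed_threshold, buried_threshold)


@dataclass
class ResidueMapping:
    """Bijective map between canonical residue numbers and structure
    residue numbers, built by global pairwise alignment."""

    canonical_to_structure: dict[int, tuple[str, int]]
    identity: float

    def structure_residue(self, canonical: int) -> tuple[str, int]:
        if canonical not in self.canonical_to_structure:
            raise KeyError(f"canonical position {canonical} not mapped to the structure")
        return self.canonical_to_structure[canonical]


def map_alignment_to_structure(
    fragment: MultipleAlignment,
    structure: ProteinStructure,
    chain: str | None = None,
    min_identity: float = 0.3,
) -> ResidueMapping:
    """Map the fragment's canonical numbering onto structure residue numbers.

    The (ungapped) reference sequence of the fragment is globally aligned to
    the structure's chain sequence with BLOSUM62 (gap open -11, extend -1);
    aligned non-gap pairs define the mapping. An identity below
    ``min_identity`` is treated as a wrong-structure error; the default
    floor is permissive enough for paralog-level homology.
    """
    ref = fragment.reference_record()
    frag_seq = ref.residues.replace("-", "").replace(".", "")
    canon_numbers = [fragment.numbering_map[c] for c in sorted(fragment.numbering_map)]
    struct_seq, struct_numbers = structure.chain_sequence(chain)
    struct_chain = structure.residues[0].chain if chain is None else chain
    if not struct_seq:
        raise ValueError("structure has no polypeptide chain")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    aln = aligner.align(frag_seq.replace("X", "A"), struct_seq.replace("X", "A"))[0]
    mapping: dict[int, tuple[str, int]] = {}
    matches = aligned_total = 0
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for off in range(a_end - a_start):
            ai, bi = a_start + off, b_start + off
            mapping[canon_numbers[ai]] = (struct_chain, struct_numbers[bi])
            aligned_total += 1
            if frag_seq[ai] == struct_seq[bi]:
                matches += 1
    identity = matches / aligned_total if aligned_total else 0.0
    if identity < min_identity:
        raise ValueError(
            f"fragment/structure identity {identity:.2f} below floor {min_identity:.2f}; "
            "is this the right structure?"
        )
    return ResidueMapping(mapping, identity)


def select_atoms(
    structure: ProteinStructure,
    chain: str | None = None,
    residue_numbers: list[int] | None = None,
    residue_names: list[str] | None = None,
    atom_names: list[str] | None = None,
) -> np.ndarray:
    """Coordinates of atoms matching the (chain, residue, atom-name) filter."""
    coords = []
    for res in structure.residues:
        if chain is not None and res.chain != chain:
            continue
        if residue_numbers is not None and res.number not in residue_numbers:
            continue
        if residue_names is not None and res.name.upper() not in {n.upper() for n in residue_names}:
            continue
        for atom in res.atoms:
            if atom_names is not None and atom.name not in atom_names:
                continue
            coords.append(atom.coord)
    return np.array(coords)


def min_distance(selection_a: np.ndarray, selection_b: np.ndarray) -> float:
    """Minimum Euclidean distance (Å) between two atom coordinate sets."""
    a, b = np.atleast_2d(selection_a), np.atleast_2d(selection_b)
    if a.size == 0:
        raise ValueError("first atom selection is empty")
    if b.size == 0:
        raise ValueError("second atom selection is empty")
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    return float(d.min())
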