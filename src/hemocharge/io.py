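"""Readers, writers and cross-validation for the pipeline's external formats.

Formats handled: FASTA alignments (protein or in-frame nucleotide), newick
trees, PDB structures (ATOM records), and two TSV tables — species metadata
(sample code, species, family, climate class) and externally computed
per-site selection-test results.

Residue positions throughout the package are expressed in a canonical
1-based numbering anchored to a designated reference record of each
alignment (for the octopod haemocyanin study this is the full Enteroctopus
dofleini sequence, UniProt O61363, under which the analysed fragments span
positions 2306–2708).
"""

from __future__ import annotations

import io as _stdio
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDE_ALPHABET = set("ACGTUN")
GAP_CHARS = set("-.")

#: Fixed van der Waals radii (Å) by element, used for all SASA work.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}

CLIMATE_ORDER = ("polar", "temperate", "subtropical", "tropical")
CLIMATE_ORDINAL = {c: i for i, c in enumerate(CLIMATE_ORDER)}

#: Default "SpeciesCode_CloneId" record-id convention.
DEFAULT_ID_PATTERN = re.compile(r"^(?P<species>[^_]+)(?:_(?P<clone>.+))?$")

KNOWN_TESTS = ("SLAC", "FEL", "MEME", "FUBAR", "EF", "PRIME", "TreeSAAP")
STATISTIC_KINDS = ("p_value", "posterior_probability", "bayes_factor", "magnitude_zscore")


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class AlignmentRecord:
    id: str
    species_code: str
    clone_id: str
    residues: str


@dataclass
class MultipleAlignment:
    """Equal-length gapped sequences plus a canonical numbering map.

    ``numbering_map`` maps 0-based column index -> canonical residue number
    for columns where the reference record has a residue; reference-gap
    columns carry no canonical number.
    """

    records: list[AlignmentRecord]
    alphabet: str  # "protein" | "nucleotide"
    reference_id: str | None = None
    canonical_start: int = 1
    numbering_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("alignment has no records")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            bad = [r.id for r in self.records if len(r.residues) != len(self.records[0].residues)]
            raise FormatError(f"ragged alignment: records {bad} differ in length")
        legal = (PROTEIN_ALPHABET if self.alphabet == "protein" else NUCLEOTIDE_ALPHABET) | GAP_CHARS
        for r in self.records:
            for pos, ch in enumerate(r.residues.upper()):
                if ch not in legal and ch != "X":
                    raise FormatError(
                        f"illegal {self.alphabet} character {ch!r} in record {r.id} at column {pos + 1}"
                    )
        if not self.numbering_map:
            self.numbering_map = self._build_numbering_map()

    def _build_numbering_map(self) -> dict[int, int]:
        ref = self.reference_record()
        mapping: dict[int, int] = {}
        num = self.canonical_start
        for col, ch in enumerate(ref.residues):
            if ch not in GAP_CHARS:
                mapping[col] = num
                num += 1
        return mapping

    def reference_record(self) -> AlignmentRecord:
        if self.reference_id is None:
            return self.records[0]
        for r in self.records:
            if r.id == self.reference_id:
                return r
        raise FormatError(f"reference record {self.reference_id!r} not in alignment")

    @property
    def column_count(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, index: int) -> str:
        if not 0 <= index < self.column_count:
            raise IndexError(f"column {index} out of range 0..{self.column_count - 1}")
        return "".join(r.residues[index] for r in self.records)

    def canonical_to_column(self) -> dict[int, int]:
        return {num: col for col, num in self.numbering_map.items()}


def _split_record_id(record_id: str, pattern: re.Pattern) -> tuple[str, str]:
    m = pattern.match(record_id)
    if not m:
        return record_id, ""
    species = m.group("species")
    clone = m.group("clone") or ""
    return species, clone


def read_fasta_alignment(
    path: str | Path,
    alphabet: str = "protein",
    reference_id: str | None = None,
    canonical_start: int = 1,
    id_pattern: re.Pattern = DEFAULT_ID_PATTERN,
) -> MultipleAlignment:
    """Parse an aligned FASTA file into a :class:`MultipleAlignment`.

    Record ids are split into species code and clone id at the first
    underscore (configurable via ``id_pattern``). Raggedness and illegal
    characters are hard errors naming the offending record/position.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        species, clone = _split_record_id(rec.id, id_pattern)
        records.append(AlignmentRecord(rec.id, species, clone, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return MultipleAlignment(
        records=records,
        alphabet=alphabet,
        reference_id=reference_id,
        canonical_start=canonical_start,
    )


def write_fasta_alignment(alignment: MultipleAlignment, path: str | Path) -> None:
    recs = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in alignment.records]
    SeqIO.write(recs, str(path), "fasta")


@dataclass
class PhyloTree:
    """Thin wrapper around a dendropy tree with non-negative branch lengths."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def total_length(self) -> float:
        return sum(e.length or 0.0 for e in self.tree.edges() if e.head_node.parent_node)

    @property
    def n_edges(self) -> int:
        return sum(1 for e in self.tree.edges() if e.head_node.parent_node)

    def check_matches_alignment(self, alignment: MultipleAlignment) -> None:
        missing = set(self.tip_labels) - set(alignment.ids)
        if missing:
            raise FormatError(f"tree tips missing from alignment: {sorted(missing)}")


def read_newick(path_or_string: str | Path) -> PhyloTree:
    """Read a newick tree; missing branch lengths default to 0 with a warning."""
    text = str(path_or_string)
    if not text.strip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises its own hierarchy
        raise FormatError(f"newick parse error: {exc}") from exc
    n_missing = 0
    for edge in tree.edges():
        if edge.head_node.parent_node is None:
            continue
        if edge.length is None:
            edge.length = 0.0
            n_missing += 1
        elif edge.length < 0:
            raise FormatError("negative branch length in tree")
    if n_missing:
        log.warning("%d branches had no length; defaulted to 0", n_missing)
    return PhyloTree(tree)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.tree.as_string(schema="newick"))


@dataclass
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float
    radius: float

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Residue:
    chain: str
    number: int
    name: str
    atoms: list[Atom]


@dataclass
class ProteinStructure:
    residues: list[Residue]

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def chain_sequence(self, chain: str | None = None) -> tuple[str, list[int]]:
        """(one-letter sequence, residue numbers) for a chain (default: first)."""
        from Bio.Data.IUPACData import protein_letters_3to1

        res = [r for r in self.residues if chain is None or r.chain == chain]
        if chain is None and res:
            first = res[0].chain
            res = [r for r in res if r.chain == first]
        seq, numbers = [], []
        for r in res:
            aa = protein_letters_3to1.get(r.name.capitalize(), "X")
            seq.append(aa)
            numbers.append(r.number)
        return "".join(seq), numbers


def _element_radius(element: str, atom_name: str) -> float:
    el = element.strip().upper()
    if not el:
        el = atom_name.strip()[0].upper()
    if el not in VDW_RADII:
        raise FormatError(f"unknown element {element!r} for atom {atom_name!r}")
    return VDW_RADII[el]


def read_pdb(path: str | Path) -> ProteinStructure:
    """Read ATOM records from a PDB file (first model only).

    Alternate locations keep the highest-occupancy conformer (ties broken in
    favour of altloc 'A'); HETATM records are excluded from the residue list.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("s", str(path))
    models = list(structure.get_models())
    if not models:
        raise FormatError(f"no models in {path}")
    model = models[0]
    residues: list[Residue] = []
    n_het = 0
    for chain in model:
        for res in chain:
            hetflag = res.id[0]
            if hetflag != " ":
                n_het += 1
                continue
            atoms: list[Atom] = []
            for atom in res:
                if atom.is_disordered():
                    children = sorted(
                        atom.disordered_get_list(),
                        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                    )
                    atom = children[0]
                x, y, z = (float(v) for v in atom.coord)
                if not all(np.isfinite([x, y, z])):
                    raise FormatError(f"non-finite coordinates for atom {atom.get_name()}")
                atoms.append(
                    Atom(
                        name=atom.get_name(),
                        element=atom.element or atom.get_name()[0],
                        x=x,
                        y=y,
                        z=z,
                        radius=_element_radius(atom.element or "", atom.get_name()),
                    )
                )
            residues.append(Residue(chain.id, res.id[1], res.get_resname(), atoms))
    if not residues:
        if n_het:
            log.warning("%s contains only HETATM records; zero protein residues", path)
            return ProteinStructure(residues=[])
        raise FormatError(f"no ATOM records in {path}")
    return ProteinStructure(residues=residues)


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write a minimal PDB file (ATOM records only)."""
    lines = []
    serial = 1
    for res in structure.residues:
        for atom in res.atoms:
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {serial:>5d} {name:<4s}{res.name:>4s} {res.chain}{res.number:>4d}    "
                f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class SpeciesTable:
    """species_code -> (species, family, climate class) with an ordinal coding
    polar=0 < temperate=1 < subtropical=2 < tropical=3 ("warmer" is larger)."""

    table: pd.DataFrame  # columns: species_code, species, family, climate, climate_ordinal

    def climate_of(self, species_code: str) -> str:
        row = self.table[self.table.species_code == species_code]
        if row.empty:
            raise KeyError(f"species code {species_code!r} not in species table")
        return row.climate.iloc[0]

    def ordinal_of(self, species_code: str) -> int:
        return CLIMATE_ORDINAL[self.climate_of(species_code)]

    def check_covers_alignment(self, alignment: MultipleAlignment) -> None:
        known = set(self.table.species_code)
        missing = {r.species_code for r in alignment.records} - known
        if missing:
            raise FormatError(f"alignment species codes missing from table: {sorted(missing)}")


def read_species_table(path: str | Path) -> SpeciesTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species_code", "species", "family", "climate"}
    if not required.issubset(df.columns):
        raise FormatError(f"species table needs columns {sorted(required)}, got {list(df.columns)}")
    bad = set(df.climate) - set(CLIMATE_ORDER)
    if bad:
        raise FormatError(f"unknown climate label(s): {sorted(bad)}")
    df = df.copy()
    df["climate_ordinal"] = df.climate.map(CLIMATE_ORDINAL)
    return SpeciesTable(df)


def write_species_table(table: SpeciesTable, path: str | Path) -> None:
    table.table.drop(columns=["climate_ordinal"]).to_csv(path, sep="\t", index=False)


@dataclass
class ExternalTestTable:
    """Per-site results of externally run selection tests (one row per
    site × test), with the statistic kind made explicit so thresholds are
    applied in the right direction."""

    table: pd.DataFrame  # columns: site, test, direction, kind, value


_KIND_FOR_TEST = {
    "SLAC": "p_value",
    "FEL": "p_value",
    "MEME": "p_value",
    "PRIME": "p_value",
    "FUBAR": "posterior_probability",
    "EF": "bayes_factor",
    "TreeSAAP": "magnitude_zscore",
}


def read_test_table(path: str | Path) -> ExternalTestTable:
    df = pd.read_csv(path, sep="\t")
    required = {"site", "test", "direction", "kind", "value"}
    if not required.issubset(df.columns):
        raise FormatError(f"test table needs columns {sorted(required)}, got {list(df.columns)}")
    bad_tests = set(df.test) - set(KNOWN_TESTS)
    if bad_tests:
        raise FormatError(f"unknown test name(s): {sorted(bad_tests)}")
    bad_kinds = set(df.kind) - set(STATISTIC_KINDS)
    if bad_kinds:
        raise FormatError(f"unknown statistic kind(s): {sorted(bad_kinds)}")
    for _, row in df.iterrows():
        expected = _KIND_FOR_TEST[row.test]
        if row.kind not in (expected, "magnitude_zscore"):
            if not (row.test == "TreeSAAP" and row.kind == "magnitude_zscore"):
                raise FormatError(
                    f"test {row.test} expects statistic kind {expected}, got {row.kind}"
                )
        if row.kind in ("p_value", "posterior_probability") and not 0.0 <= row.value <= 1.0:
            raise FormatError(
                f"{row.kind} out of [0,1] for site {row.site}, test {row.test}: {row.value}"
            )
        if row.direction not in ("positive", "negative"):
            raise FormatError(f"bad direction {row.direction!r} for site {row.site}")
    dup = df.duplicated(subset=["site", "test", "direction"])
    if dup.any():
        raise FormatError(f"duplicate (site, test) rows: {df[dup][['site', 'test']].values.tolist()}")
    return ExternalTestTable(df)


def write_test_table(table: ExternalTestTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def validate_inputs(
    alignment: MultipleAlignment | None = None,
    tree: PhyloTree | None = None,
    species: SpeciesTable | None = None,
) -> list[str]:
    """Cross-validate whatever subset of inputs is supplied; returns a list of
    human-readable problems (empty when consistent)."""
    problems: list[str] = []
    if alignment is not None and tree is not None:
        try:
            tree.check_matches_alignment(alignment)
        except FormatError as exc:
            problems.append(str(exc))
    if alignment is not None and species is not None:
        try:
            species.check_covers_alignment(alignment)
        except FormatError as exc:
            problems.append(str(exc))
    return problems
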