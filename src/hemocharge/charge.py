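"""Henderson–Hasselbalch residue charges, net surface charge, titration
("buffer line") curves, polar-residue censuses and the alpha-stat pH model.

A titratable side chain's fractional charge at a given pH follows directly
from its pKa:

    basic  (His, Lys, Arg):      +1 / (1 + 10^(pH - pKa))
    acidic (Asp, Glu, Cys, Tyr): -1 / (1 + 10^(pKa - pH))

Net charge of a residue subset is the sum of these fractions; termini are
not titrated (the analysed haemocyanin regions are internal fragments). An
integer-charge mode (±1 for Asp/Glu/Lys/Arg and +1 for His) is available
because published charge counts are sometimes integer tallies.

The alpha-stat model describes how ectotherm haemolymph pH tracks
temperature along the imidazole buffer line: pH(T) = 7.27 - 0.0153*(T - 10)
with the reference venous pH 7.27 at 10 °C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GAP_CHARS, MultipleAlignment

#: Default side-chain pKa values; acidic residues carry negative charge when
#: deprotonated, basic residues positive charge when protonated.
DEFAULT_PKA = {
    "D": (3.65, "acidic"),
    "E": (4.25, "acidic"),
    "C": (8.50, "acidic"),
    "Y": (10.10, "acidic"),
    "H": (6.50, "basic"),
    "K": (10.80, "basic"),
    "R": (12.50, "basic"),
}

#: Polar residue types tallied by the census.
POLAR_RESIDUES = "DEHKRSTNQCY"

#: Alpha-stat defaults: slope in pH units per °C and the (10 °C, pH 7.27)
#: venous reference point.
ALPHA_STAT_SLOPE = -0.0153
ALPHA_STAT_REF_TEMP = 10.0
ALPHA_STAT_REF_PH = 7.27


@dataclass
class PkaTable:
    values: dict[str, tuple[float, str]] = field(default_factory=lambda: dict(DEFAULT_PKA))

    def __post_init__(self) -> None:
        for aa, (pka, kind) in self.values.items():
            if not 0.0 < pka < 14.0:
                raise ValueError(f"pKa for {aa} out of (0, 14): {pka}")
            if kind not in ("acidic", "basic"):
                raise ValueError(f"kind for {aa} must be acidic or basic, got {kind!r}")


def residue_charge(residue: str, pH: float, pka_table: PkaTable | None = None) -> float:
    """Fractional Henderson–Hasselbalch charge of one residue at a given pH.

    Non-titratable residues (and gaps) return 0.
    """
    table = (pka_table or PkaTable()).values
    entry = table.get(residue.upper())
    if entry is None:
        return 0.0
    pka, kind = entry
    if kind == "basic":
        return 1.0 / (1.0 + 10.0 ** (pH - pka))
    return -1.0 / (1.0 + 10.0 ** (pka - pH))


def integer_residue_charge(residue: str) -> int:
    """Integer charge convention: -1 for Asp/Glu, +1 for Lys/Arg/His, else 0."""
    r = residue.upper()
    if r in "DE":
        return -1
    if r in "KRH":
        return 1
    return 0


def net_charge(
    sequence: str,
    position_subset: list[int] | None = None,
    pH: float = 7.27,
    pka_table: PkaTable | None = None,
    mode: str = "fractional",
) -> float:
    """Net charge of a sequence (or a 1-based position subset of it).

    Gaps contribute nothing; termini are not titrated. ``mode`` selects
    fractional Henderson–Hasselbalch charges (default) or integer charges.
    """
    positions = range(1, len(sequence) + 1) if position_subset is None else position_subset
    total = 0.0
    for pos in positions:
        if not 1 <= pos <= len(sequence):
            raise IndexError(f"position {pos} outside sequence of length {len(sequence)}")
        ch = sequence[pos - 1]
        if ch in GAP_CHARS:
            continue
        if mode == "integer":
            total += integer_residue_charge(ch)
        else:
            total += residue_charge(ch, pH, pka_table)
    return total


@dataclass
class ChargeProfile:
    """Net charge as a function of pH for one sequence/subset."""

    label: str
    ph_grid: np.ndarray
    net_charge: np.ndarray

    def isoelectric_point(self) -> float | None:
        """pH at which the curve crosses zero (linear interpolation on the
        grid); None if the curve never changes sign."""
        s = np.sign(self.net_charge)
        idx = np.flatnonzero(np.diff(s) != 0)
        if len(idx) == 0:
            return None
        i = idx[0]
        x0, x1 = self.ph_grid[i], self.ph_grid[i + 1]
        y0, y1 = self.net_charge[i], self.net_charge[i + 1]
        if y1 == y0:
            return float(x0)
        return float(x0 - y0 * (x1 - x0) / (y1 - y0))


def titration_curve(
    sequence: str,
    position_subset: list[int] | None = None,
    ph_range: tuple[float, float] = (4.0, 10.0),
    step: float = 0.05,
    pka_table: PkaTable | None = None,
    label: str = "",
) -> ChargeProfile:
    """Buffer line: net charge on a pH grid (monotone non-increasing)."""
    lo, hi = ph_range
    if not (0.0 < lo < hi < 14.0):
        raise ValueError("pH range must satisfy 0 < lo < hi < 14")
    grid = np.arange(lo, hi + step / 2, step)
    charges = np.array(
        [net_charge(sequence, position_subset, ph, pka_table) for ph in grid]
    )
    return ChargeProfile(label=label, ph_grid=grid, net_charge=charges)


@dataclass
class PolarResidueCensus:
    """Per-record polar-residue counts over a surface position set plus net
    charge (fractional and integer) at the reference pH."""

    table: pd.DataFrame
    reference_ph: float


def polar_census(
    alignment: MultipleAlignment,
    surface_positions: list[int],
    reference_ph: float = 7.27,
    pka_table: PkaTable | None = None,
) -> PolarResidueCensus:
    """Count each polar residue type at the surface positions of every record
    and evaluate the net charge there at the reference pH.

    ``surface_positions`` are canonical residue numbers (translated through
    the alignment's numbering map); a gap at a surface position contributes
    nothing.
    """
    canon_to_col = alignment.canonical_to_column()
    cols = []
    for pos in surface_positions:
        if pos not in canon_to_col:
            raise KeyError(f"surface position {pos} not in the alignment's numbering map")
        cols.append(canon_to_col[pos])
    rows = []
    for rec in alignment.records:
        counts = {aa: 0 for aa in POLAR_RESIDUES}
        frac = 0.0
        integer = 0
        for col in cols:
            ch = rec.residues[col]
            if ch in GAP_CHARS:
                continue
            if ch in counts:
                counts[ch] += 1
            frac += residue_charge(ch, reference_ph, pka_table)
            integer += integer_residue_charge(ch)
        row = {"record_id": rec.id, "species_code": rec.species_code}
        row.update({f"n_{aa}": counts[aa] for aa in POLAR_RESIDUES})
        row["net_charge"] = frac
        row["net_charge_integer"] = integer
        rows.append(row)
    return PolarResidueCensus(pd.DataFrame(rows), reference_ph)


@dataclass
class AlphaStatModel:
    """Linear haemolymph pH–temperature relation along the imidazole buffer
    line; slope must be negative (pH rises as temperature falls)."""

    slope: float = ALPHA_STAT_SLOPE
    reference_temp: float = ALPHA_STAT_REF_TEMP
    reference_ph: float = ALPHA_STAT_REF_PH

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("alpha-stat slope must be negative")


def ph_alpha_stat(temperature: float, model: AlphaStatModel | None = None) -> float:
    """Haemolymph pH predicted at a body temperature (°C)."""
    m = model or AlphaStatModel()
    if not -2.0 <= temperature <= 35.0:
        warnings.warn(
            f"temperature {temperature} °C outside the physiological range (-2..35)",
            stacklevel=2,
        )
    return m.reference_ph + m.slope * (temperature - m.reference_temp)
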