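"""Per-column conservation scoring with the Jensen–Shannon divergence.

Each alignment column's amino-acid distribution is compared against a fixed
background (by default the BLOSUM62 amino-acid frequencies), giving a score
in [0, 1] where larger means more conserved (further from background, i.e.
closer to a point mass). Gappy columns are down-weighted by the fraction of
gaps, and a windowed variant mixes in the mean score of neighbouring
columns so runs of conserved sites reinforce one another.

The column score is

    S(c) = (1 - g_c) * JSD(p_c, q)

with g_c the gap fraction, p_c the observed column distribution, q the
background, and JSD the Jensen-Shannon divergence with base-2 logarithms
(0 <= JSD <= 1; 0*log 0 := 0). The windowed score is

    W(i) = (1 - lambda) * S(i) + lambda * mean{ S(j) : 0 < |i - j| <= w }

truncated at the alignment edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GAP_CHARS, MultipleAlignment

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: BLOSUM62 background amino-acid frequencies (Henikoff & Henikoff marginals).
BLOSUM62_BACKGROUND = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}


def background_vector(frequencies: dict[str, float] | None = None) -> np.ndarray:
    """Validated background distribution as a vector over the 20 amino acids."""
    freqs = frequencies if frequencies is not None else BLOSUM62_BACKGROUND
    if set(freqs) != set(AMINO_ACIDS):
        raise ValueError("background must cover exactly the 20 standard amino acids")
    vec = np.array([freqs[aa] for aa in AMINO_ACIDS], dtype=float)
    if (vec <= 0).any():
        raise ValueError("background probabilities must be positive")
    if abs(vec.sum() - 1.0) > 1e-9:
        raise ValueError(f"background must sum to 1 (got {vec.sum():.12f})")
    return vec


def column_distribution(alignment: MultipleAlignment, column: int) -> tuple[np.ndarray, float]:
    """(probability vector over the 20 amino acids, gap fraction) for a column.

    The vector sums to 1 over the non-gap symbols; an all-gap column returns
    the zero vector (flagged by summing to 0) and gap fraction 1.
    """
    col = alignment.column(column)
    counts = np.zeros(len(AMINO_ACIDS))
    gaps = 0
    for ch in col:
        if ch in GAP_CHARS:
            gaps += 1
        elif ch in _AA_INDEX:
            counts[_AA_INDEX[ch]] += 1
        else:  # ambiguous residue (X): treated as missing
            gaps += 1
    total = counts.sum()
    gap_fraction = gaps / len(col)
    if total == 0:
        return counts, gap_fraction
    return counts / total, gap_fraction


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def jsd_score(
    column_dist: np.ndarray, background: np.ndarray, gap_fraction: float = 0.0
) -> float:
    """Gap-penalised Jensen–Shannon divergence of a column distribution from
    the background, in [0, 1]. An empty (all-gap) column scores 0."""
    if column_dist.sum() == 0:
        return 0.0
    m = 0.5 * (column_dist + background)
    jsd = 0.5 * _kl(column_dist, m) + 0.5 * _kl(background, m)
    return (1.0 - gap_fraction) * jsd


@dataclass
class ConservationProfile:
    """Per-column conservation scores for one alignment."""

    jsd: np.ndarray
    windowed: np.ndarray
    gap_fraction: np.ndarray
    numbering_map: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for col in range(len(self.jsd)):
            rows.append(
                {
                    "column": col,
                    "canonical_position": self.numbering_map.get(col),
                    "jsd": self.jsd[col],
                    "windowed_jsd": self.windowed[col],
                    "gap_fraction": self.gap_fraction[col],
                }
            )
        return pd.DataFrame(rows)


def windowed_scores(scores: np.ndarray, window_size: int, window_weight: float) -> np.ndarray:
    """Mix each score with the mean of its neighbours within ``window_size``
    columns each side (window truncated at the edges; the centre column is
    excluded from the neighbourhood mean)."""
    if window_size < 0:
        raise ValueError("window_size must be >= 0")
    if not 0.0 <= window_weight <= 1.0:
        raise ValueError("window_weight must be in [0, 1]")
    if window_size == 0 or window_weight == 0.0:
        return scores.copy()
    n = len(scores)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - window_size), min(n, i + window_size + 1)
        neighbours = [scores[j] for j in range(lo, hi) if j != i]
        mean = float(np.mean(neighbours)) if neighbours else scores[i]
        out[i] = (1.0 - window_weight) * scores[i] + window_weight * mean
    return out


def conservation_profile(
    alignment: MultipleAlignment,
    background: dict[str, float] | np.ndarray | None = None,
    window_size: int = 3,
    window_weight: float = 0.5,
) -> ConservationProfile:
    """Full conservation profile of a protein alignment.

    Defaults follow the scoring scheme's published defaults: window of 3
    columns each side mixed at weight 0.5, BLOSUM62 background, uniform row
    weights (no sequence weighting).
    """
    if alignment.alphabet != "protein":
        raise ValueError("conservation profile requires a protein alignment")
    q = background if isinstance(background, np.ndarray) else background_vector(background)
    n = alignment.column_count
    jsd = np.zeros(n)
    gaps = np.zeros(n)
    for col in range(n):
        p, g = column_distribution(alignment, col)
        gaps[col] = g
        jsd[col] = jsd_score(p, q, g)
    win = windowed_scores(jsd, window_size, window_weight)
    return ConservationProfile(jsd=jsd, windowed=win, gap_fraction=gaps,
                               numbering_map=dict(alignment.numbering_map))
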