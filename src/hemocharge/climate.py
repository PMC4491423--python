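"""Composition PCA, ordinal climate correlation and per-site residue
frequency summaries by climate group.

Climate of origin is an ordered factor (polar < temperate < subtropical <
tropical, coded 0..3 so "warmer" is larger). Association between a
per-record quantity (e.g. net surface charge) and climate uses Kendall's
tau-b, which handles the heavy ties an ordinal coding produces; under the
package's coding a negative tau means the quantity decreases toward warmer
climates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kendalltau
from sklearn.decomposition import PCA

from .io import GAP_CHARS, CLIMATE_ORDER, MultipleAlignment, SpeciesTable
from .charge import PolarResidueCensus

log = logging.getLogger(__name__)


@dataclass
class CompositionMatrix:
    """Rows = sequence records, columns = polar residue-type counts plus net
    charge, annotated with species/family/climate."""

    data: pd.DataFrame  # numeric block
    annotations: pd.DataFrame  # record_id, species_code, climate, climate_ordinal


def composition_matrix(
    census: PolarResidueCensus, species: SpeciesTable
) -> CompositionMatrix:
    df = census.table
    numeric = df[[c for c in df.columns if c.startswith("n_")] + ["net_charge"]].copy()
    ann = df[["record_id", "species_code"]].copy()
    ann["climate"] = [species.climate_of(sc) for sc in ann.species_code]
    ann["climate_ordinal"] = [species.ordinal_of(sc) for sc in ann.species_code]
    return CompositionMatrix(numeric.reset_index(drop=True), ann.reset_index(drop=True))


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame  # variables x components
    explained_variance_ratio: np.ndarray


def pca_composition(
    matrix: CompositionMatrix, center: bool = True, scale: bool = False,
    n_components: int | None = None,
) -> PcaResult:
    """PCA of the composition matrix (covariance by default, correlation when
    ``scale``). Component signs follow a deterministic convention: the
    largest-magnitude loading of each component is positive."""
    x = matrix.data.to_numpy(dtype=float)
    if x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("PCA needs at least 3 rows and 2 columns")
    if scale:
        sd = x.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(
                f"zero-variance column(s) with scale=True: {list(matrix.data.columns[zero])}"
            )
        x = x / sd
    if not center:
        # sklearn always centers; add the mean back into the scores afterwards
        raise NotImplementedError("uncentred PCA is not supported")
    k = n_components or min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T  # variables x components
    for j in range(loadings.shape[1]):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, columns=comp_names).assign(
            record_id=matrix.annotations.record_id.values,
            climate=matrix.annotations.climate.values,
        ),
        loadings=pd.DataFrame(loadings, index=matrix.data.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


@dataclass
class CorrelationResult:
    tau_b: float
    p_value: float
    n: int
    defined: bool = True


def kendall_climate_correlation(
    values: np.ndarray | list[float], climate_ordinals: np.ndarray | list[int]
) -> CorrelationResult:
    """Kendall tau-b of a per-record quantity against the ordinal climate
    coding, two-sided p via the tie-adjusted normal approximation."""
    v = np.asarray(values, dtype=float)
    c = np.asarray(climate_ordinals, dtype=float)
    if len(v) != len(c):
        raise ValueError("values and climate ordinals differ in length")
    if len(v) < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(v == v[0]) or np.all(c == c[0]):
        return CorrelationResult(np.nan, np.nan, len(v), defined=False)
    tau, p = kendalltau(v, c, variant="b", method="asymptotic")
    return CorrelationResult(float(tau), float(p), len(v))


def site_composition_by_climate(
    alignment: MultipleAlignment,
    canonical_site: int,
    species: SpeciesTable,
) -> pd.DataFrame:
    """Percentage of sequences bearing each amino acid at one canonical site,
    per climate class. Gaps are reported in their own column; percentages
    are over each class's sequence count (the ``n`` column)."""
    canon_to_col = alignment.canonical_to_column()
    if canonical_site not in canon_to_col:
        raise KeyError(f"site {canonical_site} not in the alignment's numbering map")
    col = canon_to_col[canonical_site]
    by_climate: dict[str, dict[str, int]] = {}
    n_by_climate: dict[str, int] = {}
    for rec in alignment.records:
        climate = species.climate_of(rec.species_code)
        ch = rec.residues[col]
        key = "gap" if ch in GAP_CHARS else ch
        by_climate.setdefault(climate, {})
        by_climate[climate][key] = by_climate[climate].get(key, 0) + 1
        n_by_climate[climate] = n_by_climate.get(climate, 0) + 1
    rows = []
    for climate in CLIMATE_ORDER:
        if climate not in by_climate:
            log.warning("no sequences for climate class %r at site %d", climate, canonical_site)
            continue
        n = n_by_climate[climate]
        row = {"climate": climate, "n": n}
        for aa, count in sorted(by_climate[climate].items()):
            row[aa] = 100.0 * count / n
        rows.append(row)
    return pd.DataFrame(rows).fillna(0.0)
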