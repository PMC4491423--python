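"""Counting-based per-site selection analysis and multi-test consensus.

The counting analysis follows the single-ancestor counting (SLAC) scheme:
ancestral nucleotide sequences are reconstructed on a fixed tree by
per-column marginal maximum likelihood under HKY85, observed synonymous
(OS) and nonsynonymous (ON) changes are tallied branch by branch (codons
differing at several positions are scored by averaging over all stop-free
minimal mutational paths), expected proportions (ES, EN) come from each
codon's single-nucleotide mutational opportunities, and per-site two-sided
evidence is summarised by one-sided extended binomial tails. dN - dS is
normalised by the total tree length.

A likelihood companion (FEL-style) fits site-specific synonymous (alpha)
and nonsynonymous (beta) rates under a simplified MG94xHKY codon model and
tests alpha = beta with a chi-square(1) likelihood-ratio test.

Externally computed per-site results (MEME, FUBAR, EF, PRIME, TreeSAAP —
run elsewhere) are merged with the internal SLAC/FEL calls by the consensus
caller: a site is consensus-positive when at least ``min_tests`` tests are
individually significant for positive selection at their own thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import binom, chi2

from . import genetics
from .genetics import (
    CODON_INDEX,
    GENETIC_CODE,
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
    is_transition,
)
from .io import GAP_CHARS, FormatError, MultipleAlignment, PhyloTree

log = logging.getLogger(__name__)

_NT_INDEX = {nt: i for i, nt in enumerate(NUCLEOTIDES)}


@dataclass
class CodonAlignment:
    """In-frame nucleotide alignment; gaps must occupy whole codons and no
    translated record may contain an internal stop codon."""

    alignment: MultipleAlignment
    genetic_code: str = "universal"

    def __post_init__(self) -> None:
        if self.alignment.alphabet != "nucleotide":
            raise FormatError("codon alignment requires a nucleotide alignment")
        if self.alignment.column_count % 3 != 0:
            raise FormatError(
                f"alignment length {self.alignment.column_count} not divisible by 3"
            )
        for rec in self.alignment.records:
            for site in range(self.codon_count):
                codon = rec.residues[3 * site : 3 * site + 3]
                n_gap = sum(ch in GAP_CHARS for ch in codon)
                if n_gap not in (0, 3):
                    raise FormatError(
                        f"record {rec.id}: gap splits codon {site + 1} ({codon})"
                    )
                if codon in STOP_CODONS and site < self.codon_count - 1:
                    raise FormatError(
                        f"record {rec.id}: internal stop codon {codon} at codon {site + 1}"
                    )

    @property
    def codon_count(self) -> int:
        return self.alignment.column_count // 3

    def codon(self, record_index: int, site: int) -> str:
        return self.alignment.records[record_index].residues[3 * site : 3 * site + 3]

    def codons_by_id(self, site: int) -> dict[str, str]:
        return {
            rec.id: rec.residues[3 * site : 3 * site + 3]
            for rec in self.alignment.records
        }

    def canonical_site_numbers(self, canonical_start: int | None = None) -> list[int]:
        """Canonical residue number of each codon site (reference assumed
        ungapped at codon granularity for site 1..codon_count)."""
        start = canonical_start if canonical_start is not None else self.alignment.canonical_start
        return [start + i for i in range(self.codon_count)]


def empirical_base_frequencies(alignment: MultipleAlignment) -> np.ndarray:
    counts = np.zeros(4)
    for rec in alignment.records:
        for ch in rec.residues:
            if ch in _NT_INDEX:
                counts[_NT_INDEX[ch]] += 1
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def estimate_kappa(alignment: MultipleAlignment, max_pairs: int = 200) -> float:
    """Moment estimate of the transition/transversion rate ratio.

    Over sequence pairs, the observed transition (P) and transversion (Q)
    difference proportions satisfy, at low divergence,
    P/Q ~ kappa * w_ts / w_tv with w_ts = 2(pi_A pi_G + pi_C pi_T) and
    w_tv the complementary pairing weight; invert for kappa. Falls back to
    2.0 when no transversions are observed.
    """
    pi = empirical_base_frequencies(alignment)
    pi_d = dict(zip(NUCLEOTIDES, pi))
    w_ts = 2 * (pi_d["A"] * pi_d["G"] + pi_d["C"] * pi_d["T"])
    w_tv = 2 * (
        pi_d["A"] * pi_d["C"] + pi_d["A"] * pi_d["T"]
        + pi_d["C"] * pi_d["G"] + pi_d["G"] * pi_d["T"]
    )
    records = alignment.records
    ts = tv = 0
    n_pairs = 0
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            if n_pairs >= max_pairs:
                break
            a, b = records[i].residues, records[j].residues
            for x, y in zip(a, b):
                if x in _NT_INDEX and y in _NT_INDEX and x != y:
                    if is_transition(x, y):
                        ts += 1
                    else:
                        tv += 1
            n_pairs += 1
    if tv == 0 or w_ts == 0:
        return 2.0
    return max(0.1, (ts / tv) * (w_tv / w_ts))


def hky_rate_matrix(kappa: float, pi: np.ndarray) -> np.ndarray:
    q = np.zeros((4, 4))
    for i, a in enumerate(NUCLEOTIDES):
        for j, b in enumerate(NUCLEOTIDES):
            if i == j:
                continue
            q[i, j] = (kappa if is_transition(a, b) else 1.0) * pi[j]
    np.fill_diagonal(q, -q.sum(axis=1))
    # scale so mean substitution rate at stationarity is 1/unit branch length
    mu = -float(np.dot(pi, np.diag(q)))
    if mu > 0:
        q /= mu
    return q


@dataclass
class AncestralStates:
    """Marginal-ML nucleotide states for every internal node, re-assembled
    into codon sequences of the alignment's codon length."""

    sequences: dict[int, str]  # node id -> nucleotide sequence
    node_labels: dict[int, str] = field(default_factory=dict)


def reconstruct_ancestors(
    codon_aln: CodonAlignment,
    tree: PhyloTree,
    kappa: float | None = None,
    base_frequencies: np.ndarray | None = None,
) -> AncestralStates:
    """Marginal maximum-likelihood ancestral nucleotides, column by column,
    under HKY85 with empirical base frequencies.

    Ties in the marginal posterior are broken alphabetically (A<C<G<T) and
    logged. Tip gaps act as missing data. Deterministic given inputs.
    """
    aln = codon_aln.alignment
    tree.check_matches_alignment(aln)
    pi = base_frequencies if base_frequencies is not None else empirical_base_frequencies(aln)
    pi = np.asarray(pi, dtype=float)
    k = kappa if kappa is not None else estimate_kappa(aln)
    q = hky_rate_matrix(k, pi)

    pmat_cache: dict[float, np.ndarray] = {}

    def pmat(t: float) -> np.ndarray:
        if t not in pmat_cache:
            pmat_cache[t] = expm(q * max(t, 0.0))
        return pmat_cache[t]

    dtree = tree.tree
    seq_by_label = {rec.id: rec.residues for rec in aln.records}
    nodes = list(dtree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    n_cols = aln.column_count
    states: dict[int, list[str]] = {id(n): [] for n in internal}
    n_ties = 0

    for col in range(n_cols):
        down: dict[int, np.ndarray] = {}
        for node in dtree.postorder_node_iter():
            if node.is_leaf():
                ch = seq_by_label[node.taxon.label][col]
                vec = np.ones(4) if ch not in _NT_INDEX else np.zeros(4)
                if ch in _NT_INDEX:
                    vec[_NT_INDEX[ch]] = 1.0
                down[id(node)] = vec
            else:
                vec = np.ones(4)
                for child in node.child_nodes():
                    vec = vec * (pmat(child.edge.length or 0.0) @ down[id(child)])
                down[id(node)] = vec
        up: dict[int, np.ndarray] = {id(dtree.seed_node): pi.copy()}
        for node in dtree.preorder_node_iter():
            if node.is_leaf():
                continue
            for child in node.child_nodes():
                if child.is_leaf():
                    continue
                sib = np.ones(4)
                for other in node.child_nodes():
                    if other is child:
                        continue
                    sib = sib * (pmat(other.edge.length or 0.0) @ down[id(other)])
                msg = up[id(node)] * sib
                up[id(child)] = msg @ pmat(child.edge.length or 0.0)
        for node in internal:
            post = up[id(node)] * down[id(node)]
            best = float(post.max())
            winners = np.flatnonzero(post >= best * (1 - 1e-12))
            if len(winners) > 1:
                n_ties += 1
            states[id(node)].append(NUCLEOTIDES[int(winners[0])])
    if n_ties:
        log.info("ancestral reconstruction: %d tied columns broken alphabetically", n_ties)
    labels = {id(n): (n.taxon.label if n.taxon else f"node{idx}") for idx, n in enumerate(internal)}
    return AncestralStates(
        sequences={nid: "".join(chars) for nid, chars in states.items()},
        node_labels=labels,
    )


@dataclass
class SiteCounts:
    """Per-codon-site observed and expected substitution quantities."""

    table: pd.DataFrame  # site (1-based), OS, ON, ES, EN, dN, dS, dnds_diff_norm
    total_tree_length: float

    @property
    def total_substitutions(self) -> float:
        return float((self.table.OS + self.table.ON).sum())


def count_site_substitutions(
    codon_aln: CodonAlignment, tree: PhyloTree, ancestors: AncestralStates
) -> SiteCounts:
    """Tally OS/ON per site over every branch and compute ES/EN, dN, dS and
    the tree-length-normalised dN - dS.

    Multi-nucleotide codon changes are averaged over all stop-free minimal
    mutational paths; a branch/site whose every path crosses a stop codon is
    left uncounted (warned). ES/EN are each parent codon's stop-free
    synonymous/nonsynonymous mutation-target fractions, averaged over
    branches weighted by branch length.
    """
    aln = codon_aln.alignment
    n_sites = codon_aln.codon_count
    seq_by_label = {rec.id: rec.residues for rec in aln.records}

    def node_seq(node) -> str | None:
        if node.is_leaf():
            return seq_by_label.get(node.taxon.label)
        return ancestors.sequences.get(id(node))

    os_ = np.zeros(n_sites)
    on_ = np.zeros(n_sites)
    es_w = np.zeros(n_sites)
    en_w = np.zeros(n_sites)
    w_tot = np.zeros(n_sites)
    n_unresolved = 0
    total_length = tree.total_length

    for node in tree.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        pseq, cseq = node_seq(parent), node_seq(node)
        if pseq is None or cseq is None:
            continue
        blen = node.edge.length or 0.0
        for site in range(n_sites):
            pc = pseq[3 * site : 3 * site + 3]
            cc = cseq[3 * site : 3 * site + 3]
            if any(ch in GAP_CHARS or ch == "N" for ch in pc + cc):
                continue
            if pc in GENETIC_CODE and pc not in STOP_CODONS:
                es, en = genetics.codon_site_proportions(pc)
                es_w[site] += blen * es
                en_w[site] += blen * en
                w_tot[site] += blen
            steps = genetics.count_substitution_steps(pc, cc)
            if steps is None:
                if pc != cc:
                    n_unresolved += 1
                continue
            syn, nonsyn = steps
            os_[site] += syn
            on_[site] += nonsyn
    if n_unresolved:
        log.warning("%d branch/site codon changes had no stop-free path; uncounted", n_unresolved)

    with np.errstate(invalid="ignore", divide="ignore"):
        es_frac = np.where(w_tot > 0, es_w / np.maximum(w_tot, 1e-300), np.nan)
        en_frac = np.where(w_tot > 0, en_w / np.maximum(w_tot, 1e-300), np.nan)
        # per-site numbers of synonymous/nonsynonymous "sites" (of 3 nt positions)
        dn = np.where(en_frac > 0, on_ / (3 * en_frac), 0.0)
        ds = np.where(es_frac > 0, os_ / (3 * es_frac), 0.0)
    norm = (dn - ds) / total_length if total_length > 0 else np.full(n_sites, np.nan)
    table = pd.DataFrame(
        {
            "site": np.arange(1, n_sites + 1),
            "OS": os_,
            "ON": on_,
            "ES": es_frac,
            "EN": en_frac,
            "dN": dn,
            "dS": ds,
            "dnds_diff_norm": norm,
        }
    )
    return SiteCounts(table=table, total_tree_length=total_length)


def _round_half_even(x: float) -> int:
    return int(round(x))


def site_selection_test(counts: SiteCounts) -> pd.DataFrame:
    """One-sided extended binomial tests per site.

    p_positive = P[X >= ON] with X ~ Binomial(n = ON + OS, p = EN) and
    p_negative the mirror image for OS with p = ES. Fractional path-averaged
    counts are rounded half-even for the test; the fractional values stay in
    the output. Sites with no substitutions report p = 1 both ways.
    """
    rows = []
    for _, r in counts.table.iterrows():
        n = _round_half_even(r.OS + r.ON)
        k_pos = _round_half_even(r.ON)
        k_neg = _round_half_even(r.OS)
        if n <= 0 or not np.isfinite(r.EN):
            p_pos = p_neg = 1.0
        else:
            k_pos = min(k_pos, n)
            k_neg = min(k_neg, n)
            p_pos = float(binom.sf(k_pos - 1, n, r.EN)) if r.EN > 0 else 1.0
            p_neg = float(binom.sf(k_neg - 1, n, r.ES)) if r.ES > 0 else 1.0
        rows.append({"site": int(r.site), "p_positive": min(p_pos, 1.0), "p_negative": min(p_neg, 1.0)})
    return pd.DataFrame(rows)


def slac_analysis(
    codon_aln: CodonAlignment, tree: PhyloTree, kappa: float | None = None
) -> tuple[SiteCounts, pd.DataFrame]:
    """Ancestor reconstruction + counting + binomial tests in one call."""
    anc = reconstruct_ancestors(codon_aln, tree, kappa=kappa)
    counts = count_site_substitutions(codon_aln, tree, anc)
    tests = site_selection_test(counts)
    return counts, tests


# ---------------------------------------------------------------------------
# FEL-style per-site likelihood-ratio test (simplified MG94 x HKY)


class _CodonModel:
    """Site likelihood machinery for the 61-state codon model with separate
    synonymous (alpha) and nonsynonymous (beta) rate multipliers."""

    def __init__(self, kappa: float, pi_nt: np.ndarray):
        n = len(SENSE_CODONS)
        self.syn = np.zeros((n, n))
        self.nonsyn = np.zeros((n, n))
        for i, ci in enumerate(SENSE_CODONS):
            for pos in range(3):
                for nt in NUCLEOTIDES:
                    if nt == ci[pos]:
                        continue
                    cj = ci[:pos] + nt + ci[pos + 1 :]
                    if cj in STOP_CODONS:
                        continue
                    j = CODON_INDEX[cj]
                    rate = (kappa if is_transition(ci[pos], nt) else 1.0) * pi_nt[_NT_INDEX[nt]]
                    if GENETIC_CODE[ci] == GENETIC_CODE[cj]:
                        self.syn[i, j] = rate
                    else:
                        self.nonsyn[i, j] = rate
        # stationary codon frequencies proportional to products of pi_nt
        freqs = np.array(
            [pi_nt[_NT_INDEX[c[0]]] * pi_nt[_NT_INDEX[c[1]]] * pi_nt[_NT_INDEX[c[2]]]
             for c in SENSE_CODONS]
        )
        self.pi = freqs / freqs.sum()
        # scale so that alpha = beta = 1 gives one expected substitution per
        # codon site per unit branch length at stationarity
        q1 = self.syn + self.nonsyn
        mu = float(np.sum(self.pi * q1.sum(axis=1)))
        if mu > 0:
            self.syn /= mu
            self.nonsyn /= mu

    def rate_matrix(self, alpha: float, beta: float) -> np.ndarray:
        q = alpha * self.syn + beta * self.nonsyn
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def site_loglik(
        self, tree: PhyloTree, codons: dict[str, str], alpha: float, beta: float
    ) -> float:
        q = self.rate_matrix(alpha, beta)
        pcache: dict[float, np.ndarray] = {}

        def pmat(t: float) -> np.ndarray:
            if t not in pcache:
                pcache[t] = expm(q * max(t, 0.0))
            return pcache[t]

        down: dict[int, np.ndarray] = {}
        n = len(SENSE_CODONS)
        for node in tree.tree.postorder_node_iter():
            if node.is_leaf():
                codon = codons.get(node.taxon.label, "---")
                vec = np.ones(n)
                if codon in CODON_INDEX:
                    vec = np.zeros(n)
                    vec[CODON_INDEX[codon]] = 1.0
                down[id(node)] = vec
            else:
                vec = np.ones(n)
                for child in node.child_nodes():
                    vec = vec * (pmat(child.edge.length or 0.0) @ down[id(child)])
                down[id(node)] = vec
        lik = float(np.dot(self.pi, down[id(tree.tree.seed_node)]))
        return np.log(max(lik, 1e-300))


@dataclass
class FelResult:
    site: int
    alpha: float
    beta: float
    omega: float
    lrt: float
    p_value: float
    converged: bool


def fel_site_test(
    codon_aln: CodonAlignment,
    tree: PhyloTree,
    site: int,
    kappa: float | None = None,
    model: _CodonModel | None = None,
) -> FelResult:
    """Likelihood-ratio test of alpha = beta at one codon site (1-based).

    The alternative fits site-specific synonymous and nonsynonymous rate
    multipliers; the null constrains them equal; p comes from chi2(1).
    Invariant sites report omega = nan and p = 1 without fitting.
    """
    codons = codon_aln.codons_by_id(site - 1)
    observed = {c for c in codons.values() if c in CODON_INDEX}
    if len(observed) <= 1:
        return FelResult(site, np.nan, np.nan, np.nan, 0.0, 1.0, True)
    if model is None:
        k = kappa if kappa is not None else estimate_kappa(codon_aln.alignment)
        pi = empirical_base_frequencies(codon_aln.alignment)
        model = _CodonModel(k, pi)

    def nll_alt(x: np.ndarray) -> float:
        return -model.site_loglik(tree, codons, np.exp(x[0]), np.exp(x[1]))

    def nll_null(logmu: float) -> float:
        mu = np.exp(logmu)
        return -model.site_loglik(tree, codons, mu, mu)

    res_null = minimize_scalar(nll_null, bounds=(np.log(1e-4), np.log(50.0)), method="bounded",
                               options={"xatol": 1e-6})
    x0 = np.array([res_null.x, res_null.x])
    res_alt = minimize(nll_alt, x0, method="L-BFGS-B",
                       bounds=[(np.log(1e-4), np.log(50.0))] * 2,
                       options={"ftol": 1e-10, "gtol": 1e-8})
    converged = bool(res_alt.success and res_null.success)
    alpha, beta = float(np.exp(res_alt.x[0])), float(np.exp(res_alt.x[1]))
    lrt = max(0.0, 2.0 * (res_null.fun - res_alt.fun))
    p = float(chi2.sf(lrt, 1))
    omega = beta / alpha if alpha > 0 else np.inf
    return FelResult(site, alpha, beta, omega, lrt, p, converged)


def fel_scan(
    codon_aln: CodonAlignment, tree: PhyloTree, kappa: float | None = None
) -> pd.DataFrame:
    """FEL test over every codon site; shares one codon model across sites."""
    k = kappa if kappa is not None else estimate_kappa(codon_aln.alignment)
    pi = empirical_base_frequencies(codon_aln.alignment)
    model = _CodonModel(k, pi)
    rows = []
    for site in range(1, codon_aln.codon_count + 1):
        r = fel_site_test(codon_aln, tree, site, model=model)
        rows.append(
            {
                "site": r.site,
                "alpha": r.alpha,
                "beta": r.beta,
                "omega": r.omega,
                "p_value": r.p_value,
                "converged": r.converged,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Consensus across internal and external tests


@dataclass
class ConsensusConfig:
    """Per-test significance thresholds and the minimum number of significant
    tests for a consensus call (defaults: the study's reported thresholds)."""

    min_tests: int = 3
    p_slac: float = 0.10
    p_fel: float = 0.10
    p_meme: float = 0.10
    p_prime: float = 0.05
    pp_fubar: float = 0.90
    bf_ef: float = 0.50
    p_treesaap: float = 0.001

    def threshold_met(self, test: str, kind: str, value: float) -> bool:
        if kind == "p_value":
            limit = {"SLAC": self.p_slac, "FEL": self.p_fel,
                     "MEME": self.p_meme, "PRIME": self.p_prime}.get(test)
            return limit is not None and value <= limit
        if kind == "posterior_probability":
            return value >= self.pp_fubar
        if kind == "bayes_factor":
            return value >= self.bf_ef
        if kind == "magnitude_zscore":
            # TreeSAAP rows carry the significance field of a magnitude>=6
            # property category (magnitude filtering happens upstream)
            return value <= self.p_treesaap
        return False


def consensus_calls(
    internal_slac: pd.DataFrame | None = None,
    internal_fel: pd.DataFrame | None = None,
    external_tables: list | None = None,
    config: ConsensusConfig | None = None,
    site_numbers: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Tally significant tests per site and call the consensus.

    ``internal_slac`` is the output of :func:`site_selection_test`;
    ``internal_fel`` that of :func:`fel_scan` (its direction comes from the
    sign of beta - alpha). External tables contribute one (site, test,
    direction) row each. A site is consensus-positive when at least
    ``config.min_tests`` tests are significant in the positive direction
    (negative analogously); missing tests count as non-significant.
    ``site_numbers`` optionally maps internal 1-based codon sites to
    canonical residue numbers so internal and external results merge on one
    coordinate system.
    """
    cfg = config or ConsensusConfig()
    remap = site_numbers or {}
    sig: dict[tuple[int, str], set[str]] = {}
    seen: set[tuple[int, str]] = set()

    if internal_slac is not None:
        for _, r in internal_slac.iterrows():
            site = remap.get(int(r.site), int(r.site))
            pos_sig = r.p_positive <= cfg.p_slac
            neg_sig = r.p_negative <= cfg.p_slac
            if (site, "SLAC") in seen:
                raise FormatError(f"duplicate result for site {site}, test SLAC")
            seen.add((site, "SLAC"))
            if pos_sig:
                sig.setdefault((site, "positive"), set()).add("SLAC")
            if neg_sig:
                sig.setdefault((site, "negative"), set()).add("SLAC")
    if internal_fel is not None:
        for _, r in internal_fel.iterrows():
            site = remap.get(int(r.site), int(r.site))
            if (site, "FEL") in seen:
                raise FormatError(f"duplicate result for site {site}, test FEL")
            seen.add((site, "FEL"))
            if bool(r.get("converged", True)) and r.p_value <= cfg.p_fel:
                direction = "positive" if r.beta > r.alpha else "negative"
                sig.setdefault((site, direction), set()).add("FEL")
    for table in external_tables or []:
        for _, r in table.table.iterrows():
            site = int(r.site)
            key = (site, r.test)
            if key in seen:
                raise FormatError(f"duplicate result for site {site}, test {r.test}")
            seen.add(key)
            if cfg.threshold_met(r.test, r.kind, float(r.value)):
                sig.setdefault((site, r.direction), set()).add(r.test)

    sites = sorted({s for (s, _t) in seen})
    rows = []
    for site in sites:
        n_pos = len(sig.get((site, "positive"), ()))
        n_neg = len(sig.get((site, "negative"), ()))
        if n_pos >= cfg.min_tests:
            consensus = "positive"
        elif n_neg >= cfg.min_tests:
            consensus = "negative"
        else:
            consensus = "none"
        rows.append(
            {
                "site": site,
                "n_sig_pos": n_pos,
                "n_sig_neg": n_neg,
                "sig_pos_tests": ",".join(sorted(sig.get((site, "positive"), ()))),
                "sig_neg_tests": ",".join(sorted(sig.get((site, "negative"), ()))),
                "consensus": consensus,
            }
        )
    return pd.DataFrame(rows)
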