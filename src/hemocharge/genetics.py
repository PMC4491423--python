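"""Universal genetic code tables and codon-level counting primitives.

Everything here is deterministic bookkeeping on the 64-codon table: codon
classification, single-step mutational neighbourhoods, and enumeration of
minimal mutational paths between codons (used by the counting-based
selection analysis, which averages synonymous/nonsynonymous step counts
over all stop-free minimal paths).
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

NUCLEOTIDES = "ACGT"

# Universal (standard) genetic code, codon -> one-letter amino acid, '*' = stop.
GENETIC_CODE: dict[str, str] = {}
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, (_b1, _b2, _b3) in enumerate(
    (a, b, c) for a in _BASES for b in _BASES for c in _BASES
):
    GENETIC_CODE[_b1 + _b2 + _b3] = _AMINO[_i]

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

PURINES = frozenset("AG")


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; '*' for stop, 'X' if ambiguous/gapped."""
    codon = codon.upper()
    if codon in GENETIC_CODE:
        return GENETIC_CODE[codon]
    return "X"


def is_transition(a: str, b: str) -> bool:
    """True if a<->b is a purine-purine or pyrimidine-pyrimidine change."""
    return a != b and ((a in PURINES) == (b in PURINES))


@lru_cache(maxsize=None)
def codon_site_proportions(codon: str) -> tuple[float, float]:
    """(ES, EN): fraction of the codon's stop-free single-nucleotide mutation
    targets that are synonymous / nonsynonymous.

    Each of the 9 single-nucleotide neighbours counts equally; neighbours that
    are stop codons are excluded from the denominator. ES + EN = 1 for every
    sense codon.
    """
    aa = GENETIC_CODE[codon]
    syn = nonsyn = 0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            if GENETIC_CODE[mut] == aa:
                syn += 1
            else:
                nonsyn += 1
    total = syn + nonsyn
    if total == 0:  # cannot happen with the universal code, defensive
        return 0.5, 0.5
    return syn / total, nonsyn / total


@lru_cache(maxsize=None)
def count_substitution_steps(parent: str, child: str) -> tuple[float, float] | None:
    """Average (synonymous, nonsynonymous) step counts over all minimal
    stop-free mutational paths from ``parent`` to ``child``.

    A minimal path applies the differing positions one at a time in some
    order; orders passing through a stop codon are discarded. Returns None if
    every minimal path is blocked by a stop codon (the branch/site is then
    unresolved) or if either codon is not a sense codon.
    """
    parent, child = parent.upper(), child.upper()
    if parent not in GENETIC_CODE or child not in GENETIC_CODE:
        return None
    if parent in STOP_CODONS or child in STOP_CODONS:
        return None
    diff = [i for i in range(3) if parent[i] != child[i]]
    if not diff:
        return 0.0, 0.0
    syn_counts: list[int] = []
    nonsyn_counts: list[int] = []
    for order in permutations(diff):
        cur = parent
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + child[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            syn_counts.append(syn)
            nonsyn_counts.append(nonsyn)
    if not syn_counts:
        return None
    n = len(syn_counts)
    return sum(syn_counts) / n, sum(nonsyn_counts) / n


def codon_neighbours(codon: str) -> list[str]:
    """All stop-free single-nucleotide neighbours of a sense codon."""
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut not in STOP_CODONS:
                out.append(mut)
    return out
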