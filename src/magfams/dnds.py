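"""Purifying-selection screen: pairwise Nei–Gojobori (1986) dN/dS.

The ratio is used only as a pass/fail purifying-selection filter
(families with dN/dS above 0.5 are discarded), so a deterministic
counting estimator is sufficient: synonymous and non-synonymous sites are
counted per codon (averaged over the two sequences of a pair), codon
differences are resolved by averaging over all minimal mutational
pathways, and the proportions are Jukes–Cantor corrected,
``d = -3/4 * ln(1 - 4p/3)``.

Conventions for degenerate cases:

* codons containing gaps, ambiguity characters or stops in either sequence
  of a pair are excluded from that pair;
* mutational pathways passing through a stop codon get zero weight; if
  every pathway for a codon pair is blocked, all pathways are used;
* ``p >= 3/4`` saturates the correction -> ``d = +inf``;
* family ratio: mean pairwise dN over mean pairwise dS; ``0/0 -> 0``,
  ``x/0 -> +inf`` for ``x > 0``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional

from Bio.Data import CodonTable

from .model import AlignmentMatrix, GeneFamily

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_BASES = "ACGT"


def _translate(codon: str) -> Optional[str]:
    """Amino acid for a codon, None for stops."""
    if codon in _STOPS:
        return None
    return _TABLE.forward_table[codon]


def _is_valid_codon(codon: str) -> bool:
    return (
        len(codon) == 3
        and all(b in _BASES for b in codon)
        and codon not in _STOPS
    )


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts for one codon.

    Each position contributes one site, split by the fraction of
    single-nucleotide changes at that position that are synonymous;
    changes creating stop codons are excluded from the fraction.
    """
    aa = _translate(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant in _STOPS:
                continue
            valid += 1
            if _translate(mutant) == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) difference counts between two codons,
    averaged over all minimal mutational pathways (stop-free pathways only,
    unless all are blocked)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        current = c1
        syn = 0.0
        nonsyn = 0.0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in _STOPS:
                through_stop = True
            if _translate(current) is not None and _translate(nxt) is not None:
                if _translate(current) == _translate(nxt):
                    syn += 1
                else:
                    nonsyn += 1
            else:
                nonsyn += 1
            current = nxt
        pathways.append((syn, nonsyn, through_stop))
    open_paths = [p for p in pathways if not p[2]]
    if not open_paths:
        open_paths = pathways
    sd = sum(p[0] for p in open_paths) / len(open_paths)
    nd = sum(p[1] for p in open_paths) / len(open_paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; saturates to +inf at p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_pair(cds_a: str, cds_b: str) -> tuple[float, float, float, float]:
    """NG86 estimates for one aligned codon-sequence pair.

    Returns ``(pN, pS, dN, dS)``. Sequences must be equal length and a
    multiple of 3; codon positions with gaps, ambiguity or stops in either
    sequence are excluded pairwise.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences must have equal length")
    if len(cds_a) % 3 != 0:
        raise ValueError("sequence length must be divisible by 3")
    cds_a = cds_a.upper()
    cds_b = cds_b.upper()
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        c1, c2 = cds_a[i : i + 3], cds_b[i : i + 3]
        if not (_is_valid_codon(c1) and _is_valid_codon(c2)):
            continue
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = _codon_differences(c1, c2)
        Sd += sd
        Nd += nd
    pN = Nd / N if N > 0 else 0.0
    pS = Sd / S if S > 0 else 0.0
    return pN, pS, jukes_cantor(pN), jukes_cantor(pS)


@dataclass
class DnDsResult:
    family_id: str
    dN: float
    dS: float
    ratio: float
    n_pairs_used: int


def family_dnds(
    alignment: AlignmentMatrix, family_id: str = ""
) -> DnDsResult:
    """Family-level dN/dS: mean pairwise dN divided by mean pairwise dS.

    Gap columns are handled per pair inside :func:`ng86_pair` (the inputs
    are rows of a codon alignment). Pairs with a saturated (infinite)
    distance are excluded from the means.
    """
    if alignment.alphabet != "codon":
        raise ValueError("family_dnds requires a codon alignment")
    rows = alignment.rows
    dns: list[float] = []
    dss: list[float] = []
    n_pairs = 0
    for a, b in itertools.combinations(rows, 2):
        _, _, dn, ds = ng86_pair(a, b)
        if math.isinf(dn) or math.isinf(ds):
            continue
        dns.append(dn)
        dss.append(ds)
        n_pairs += 1
    mean_dn = sum(dns) / len(dns) if dns else 0.0
    mean_ds = sum(dss) / len(dss) if dss else 0.0
    if mean_ds == 0.0:
        ratio = 0.0 if mean_dn == 0.0 else math.inf
    else:
        ratio = mean_dn / mean_ds
    return DnDsResult(
        family_id=family_id, dN=mean_dn, dS=mean_ds, ratio=ratio, n_pairs_used=n_pairs
    )


def filter_by_dnds(
    families: Iterable[GeneFamily], max_ratio: float = 0.5
) -> list[GeneFamily]:
    """Keep families under purifying selection: ratio <= ``max_ratio``
    (the boundary itself is kept); families without an estimate are kept."""
    kept = []
    for fam in families:
        if fam.dnds is None or fam.dnds <= max_ratio:
            kept.append(fam)
    return kept
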