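"""Independent brute-force oracles used only by the test suite.

Deliberately naive and self-contained: the genetic code is hardcoded from
the standard NCBI table string (not taken from the package or Biopython),
site and pathway counting use exact rational arithmetic with recursive
enumeration, fold-change quantiles come from the closed-form Beta
identity for a ratio of independent Gammas, and Fisher p-values from
scipy's hypergeometric pmf. None of this code shares a path with the
implementation it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import cache
from itertools import permutations

from scipy import stats

_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_AA = {
    b1 + b2 + b3: _AAS[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}
SENSE = sorted(c for c, a in CODON_AA.items() if a != "*")

DAYHOFF = ("AGPST", "DENQ", "HKR", "ILMV", "FWY", "C")


def _klass(aa: str) -> int:
    for i, g in enumerate(DAYHOFF):
        if aa in g:
            return i
    raise KeyError(aa)


def _radical(a: str, b: str) -> bool:
    return _klass(a) != _klass(b)


@cache
def codon_sites(codon: str) -> tuple[Fraction, Fraction, Fraction]:
    """Exact (syn, radical, conservative) site fractions of one codon."""
    aa0 = CODON_AA[codon]
    syn = rad = con = Fraction(0)
    for pos in range(3):
        alts = [
            codon[:pos] + nt + codon[pos + 1 :]
            for nt in "ACGT"
            if nt != codon[pos]
        ]
        alts = [a for a in alts if CODON_AA[a] != "*"]
        m = len(alts)
        for a in alts:
            aa1 = CODON_AA[a]
            if aa1 == aa0:
                syn += Fraction(1, m)
            elif _radical(aa0, aa1):
                rad += Fraction(1, m)
            else:
                con += Fraction(1, m)
    return syn, rad, con


@cache
def pathway_diffs(ca: str, cb: str) -> tuple[Fraction, Fraction, Fraction]:
    """Exact (syn, radical, conservative) differences, pathway-averaged.

    Pathways through stop codons are excluded; if all are blocked, all
    pathways are used with stop-touching steps scored radical.
    """
    pos = [i for i in range(3) if ca[i] != cb[i]]
    if not pos:
        return Fraction(0), Fraction(0), Fraction(0)

    def steps(order, allow_stop):
        cur = ca
        s = r = c = 0
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            a0, a1 = CODON_AA[cur], CODON_AA[nxt]
            if a0 == "*" or a1 == "*":
                if not allow_stop:
                    return None
                r += 1
            elif a0 == a1:
                s += 1
            elif _radical(a0, a1):
                r += 1
            else:
                c += 1
            cur = nxt
        return s, r, c

    paths = [res for order in permutations(pos) if (res := steps(order, False)) is not None]
    if not paths:
        paths = [steps(order, True) for order in permutations(pos)]
    n = len(paths)
    return (
        Fraction(sum(p[0] for p in paths), n),
        Fraction(sum(p[1] for p in paths), n),
        Fraction(sum(p[2] for p in paths), n),
    )


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    if p == 0:
        return 0.0
    return -0.75 * math.log(1 - 4 * p / 3)


def _ratio(num, den):
    if num is None:
        return None
    if den is None:
        return 0.0 if num == 0 else None
    if den == 0:
        return None
    return num / den


def ng86(codons_a, codons_b) -> dict:
    """Full NG86 + radical/conservative statistics for a codon pair list."""
    S_sites = N_R = N_C = Fraction(0)
    S_diff = O_R = O_C = Fraction(0)
    for ca, cb in zip(codons_a, codons_b):
        sa, ra, cca = codon_sites(ca)
        sb, rb, ccb = codon_sites(cb)
        S_sites += Fraction(sa + sb, 2)
        N_R += Fraction(ra + rb, 2)
        N_C += Fraction(cca + ccb, 2)
        ds, dr, dc = pathway_diffs(ca, cb)
        S_diff += ds
        O_R += dr
        O_C += dc
    N_sites = N_R + N_C
    N_diff = O_R + O_C
    pN = float(N_diff / N_sites) if N_sites else 0.0
    pS = float(S_diff / S_sites) if S_sites else 0.0
    pR = float(O_R / N_R) if N_R else 0.0
    pC = float(O_C / N_C) if N_C else 0.0
    dN, dS, dR, dC = _jc(pN), _jc(pS), _jc(pR), _jc(pC)
    return {
        "S_sites": float(S_sites),
        "N_sites": float(N_sites),
        "N_R": float(N_R),
        "N_C": float(N_C),
        "S_diff": float(S_diff),
        "O_R": float(O_R),
        "O_C": float(O_C),
        "dN": dN,
        "dS": dS,
        "omega": _ratio(dN, dS),
        "dR": dR,
        "dC": dC,
        "dRdC": _ratio(dR, dC),
    }


def gfold_quantile(count_a, count_b, lib_a, lib_b, p) -> float:
    """Closed-form p-quantile of log2(rate_b/rate_a) for Gamma posteriors.

    With X ~ Gamma(count_b + 1), Y ~ Gamma(count_a + 1) independent,
    W = X/(X+Y) ~ Beta(count_b + 1, count_a + 1) and the rate ratio is
    (lib_a/lib_b) * W/(1-W), a monotone transform of W.
    """
    w = stats.beta.ppf(p, count_b + 1, count_a + 1)
    return math.log2((lib_a / lib_b) * w / (1.0 - w))


def fisher_two_sided(table) -> float:
    """Two-sided Fisher p by hypergeometric pmf summation.

    Tables whose pmf ties the observed one (exact rational equality shows
    up as a float difference far below the 1e-12 relative tolerance used
    here, since distinct pmfs in one margin family differ by at least
    1/C(n, c1)) are included, matching the exact-arithmetic definition.
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    dist = stats.hypergeom(n, r1, c1)
    p_obs = dist.pmf(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = dist.pmf(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)
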