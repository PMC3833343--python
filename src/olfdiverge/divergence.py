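"""Pairwise molecular-evolution statistics on codon-aligned ortholog pairs.

Implements the counting estimators used to compare orthologous chemosensory
genes between two sibling species:

* protein distance (p-distance, optionally Poisson-corrected),
* dN/dS by Nei–Gojobori (1986) style codon counting with Jukes–Cantor
  correction,
* dR/dC — radical vs conservative nonsynonymous rates sensu Zhang (2000),
  with radical/conservative defined by Dayhoff physicochemical classes,
* membrane-region and charged-residue substitution profiling, consuming
  externally predicted per-residue topology labels.

All statistics operate on a :class:`CodonAlignedPair`, the gap- and
stop-free codon columns of one aligned ortholog pair.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

__all__ = [
    "DEFAULT_DAYHOFF_CLASSES",
    "DEFAULT_CHARGED_SET",
    "CodonAlignedPair",
    "DayhoffPartition",
    "RegionAnnotation",
    "DivergenceEstimates",
    "prepare_pair",
    "protein_distance",
    "estimate_dn_ds",
    "estimate_dr_dc",
    "region_and_charge_profile",
    "analyze_pair",
    "translate_codons",
]

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> single-letter amino acid, with '*' for the three stop codons
CODON_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_AA[_stop] = "*"
SENSE_CODONS: tuple[str, ...] = tuple(sorted(c for c, a in CODON_AA.items() if a != "*"))
_NUCS = "ACGT"

DEFAULT_DAYHOFF_CLASSES: tuple[str, ...] = ("AGPST", "DENQ", "HKR", "ILMV", "FWY", "C")
#: residues whose replacement the profiling counts as touching a "charged" site
DEFAULT_CHARGED_SET: frozenset[str] = frozenset("ENY")

TM = "TM"
REGION_LABELS = ("TM", "inside", "outside")


def translate_codons(codons: Iterable[str]) -> str:
    return "".join(CODON_AA[c] for c in codons)


@dataclass(frozen=True)
class DayhoffPartition:
    """Partition of the 20 standard residues into physicochemical classes.

    A substitution within a class is *conservative*; across classes it is
    *radical*. The default is the six Dayhoff groups.
    """

    classes: tuple[str, ...] = DEFAULT_DAYHOFF_CLASSES

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group in self.classes:
            overlap = seen & set(group)
            if overlap:
                raise ValueError(f"residue classes overlap on {sorted(overlap)}")
            seen |= set(group)
        missing = set("ACDEFGHIKLMNPQRSTVWY") - seen
        if missing:
            raise ValueError(f"partition does not cover residues {sorted(missing)}")

    def class_of(self, residue: str) -> int:
        for i, group in enumerate(self.classes):
            if residue in group:
                return i
        raise KeyError(f"residue {residue!r} not covered by partition")

    def is_radical(self, res_a: str, res_b: str) -> bool:
        return self.class_of(res_a) != self.class_of(res_b)


@dataclass(frozen=True)
class CodonAlignedPair:
    """A validated, gap- and stop-free codon alignment of one ortholog pair.

    ``positions_a``/``positions_b`` give, for each retained codon column,
    the 0-based codon index in the *ungapped* CDS of each sequence, so that
    downstream profiling can anchor columns to per-residue annotations.
    """

    gene_id_a: str
    gene_id_b: str
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]
    positions_a: tuple[int, ...]
    positions_b: tuple[int, ...]
    species_a: str = "A"
    species_b: str = "B"
    dropped_gap_columns: int = 0
    dropped_stop_columns: int = 0

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon lists differ in length")

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)

    @property
    def protein_a(self) -> str:
        return translate_codons(self.codons_a)

    @property
    def protein_b(self) -> str:
        return translate_codons(self.codons_b)

    def swapped(self) -> "CodonAlignedPair":
        return CodonAlignedPair(
            gene_id_a=self.gene_id_b,
            gene_id_b=self.gene_id_a,
            codons_a=self.codons_b,
            codons_b=self.codons_a,
            positions_a=self.positions_b,
            positions_b=self.positions_a,
            species_a=self.species_b,
            species_b=self.species_a,
            dropped_gap_columns=self.dropped_gap_columns,
            dropped_stop_columns=self.dropped_stop_columns,
        )


@dataclass(frozen=True)
class RegionAnnotation:
    """Per-residue membrane-topology labels in ungapped protein coordinates."""

    gene_id: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = set(self.labels) - set(REGION_LABELS)
        if bad:
            raise ValueError(f"unknown region labels {sorted(bad)}")

    @classmethod
    def from_string(cls, gene_id: str, spec: str) -> "RegionAnnotation":
        """Build from a compact one-char-per-residue string: M=TM, i=inside, o=outside."""
        mapping = {"M": "TM", "i": "inside", "o": "outside"}
        return cls(gene_id, tuple(mapping[ch] for ch in spec))


@dataclass
class DivergenceEstimates:
    """All per-pair divergence statistics, with explicit undefined flags.

    ``omega``/``dRdC`` are ``None`` (never inf) when their denominator rate
    is zero; ``*_undefined`` flags mark Jukes–Cantor saturation.
    """

    gene_id_a: str
    gene_id_b: str
    n_codons: int
    p_dist: float
    d_prot: float | None
    d_prot_model: str
    dN: float | None
    dS: float | None
    omega: float | None
    N_sites: float
    S_sites: float
    N_diff: float
    S_diff: float
    N_R: float
    N_C: float
    O_R: float
    O_C: float
    dR: float | None
    dC: float | None
    dRdC: float | None
    region_tallies: dict[str, dict[str, int]] = field(default_factory=dict)
    charged_subs_total: int = 0
    charged_subs_in_TM: int = 0

    def to_row(self) -> dict:
        row = {
            "gene_id_a": self.gene_id_a,
            "gene_id_b": self.gene_id_b,
            "n_codons": self.n_codons,
            "p_dist": self.p_dist,
            "d_prot": self.d_prot,
            "d_prot_model": self.d_prot_model,
            "dN": self.dN,
            "dS": self.dS,
            "omega": self.omega,
            "N_sites": self.N_sites,
            "S_sites": self.S_sites,
            "N_diff": self.N_diff,
            "S_diff": self.S_diff,
            "N_R": self.N_R,
            "N_C": self.N_C,
            "O_R": self.O_R,
            "O_C": self.O_C,
            "dR": self.dR,
            "dC": self.dC,
            "dRdC": self.dRdC,
            "charged_subs_total": self.charged_subs_total,
            "charged_subs_in_TM": self.charged_subs_in_TM,
        }
        for region in REGION_LABELS + ("unassigned",):
            tallies = self.region_tallies.get(region, {})
            row[f"{region}_radical"] = tallies.get("radical", 0)
            row[f"{region}_conservative"] = tallies.get("conservative", 0)
        return row


# ---------------------------------------------------------------------------
# pair preparation


def prepare_pair(
    seq_a: str,
    seq_b: str,
    gene_id_a: str = "a",
    gene_id_b: str = "b",
    species_a: str = "A",
    species_b: str = "B",
) -> CodonAlignedPair:
    """Validate an aligned CDS pair and strip gap and stop codon columns.

    Both sequences must have the same aligned length, divisible by 3, over
    the alphabet {A,C,G,T,-}; gaps must occupy whole codons (the alignment
    is assumed to derive from a protein alignment). Columns containing a
    gap in either sequence are dropped, as are columns where either codon
    is a stop. The retained columns carry their ungapped codon index in
    each sequence.
    """
    seq_a = seq_a.upper().replace("U", "T")
    seq_b = seq_b.upper().replace("U", "T")
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}")
    if len(seq_a) % 3 != 0:
        raise ValueError(f"aligned length {len(seq_a)} is not a multiple of 3")
    bad = set(seq_a + seq_b) - set("ACGT-")
    if bad:
        raise ValueError(f"invalid characters in alignment: {sorted(bad)}")

    codons_a, codons_b, pos_a_list, pos_b_list = [], [], [], []
    ia = ib = 0  # ungapped codon counters
    n_gap = n_stop = 0
    for k in range(0, len(seq_a), 3):
        ca, cb = seq_a[k : k + 3], seq_b[k : k + 3]
        gap_a, gap_b = "-" in ca, "-" in cb
        if (gap_a and ca != "---") or (gap_b and cb != "---"):
            raise ValueError(f"gap does not span a whole codon at column {k // 3}")
        if gap_a or gap_b:
            n_gap += 1
        elif CODON_AA[ca] == "*" or CODON_AA[cb] == "*":
            n_stop += 1
        else:
            codons_a.append(ca)
            codons_b.append(cb)
            pos_a_list.append(ia)
            pos_b_list.append(ib)
        if not gap_a:
            ia += 1
        if not gap_b:
            ib += 1
    return CodonAlignedPair(
        gene_id_a=gene_id_a,
        gene_id_b=gene_id_b,
        codons_a=tuple(codons_a),
        codons_b=tuple(codons_b),
        positions_a=tuple(pos_a_list),
        positions_b=tuple(pos_b_list),
        species_a=species_a,
        species_b=species_b,
        dropped_gap_columns=n_gap,
        dropped_stop_columns=n_stop,
    )


# ---------------------------------------------------------------------------
# protein distance


def protein_distance(pair: CodonAlignedPair, correction: str = "poisson") -> tuple[float, float | None]:
    """p-distance and (optionally Poisson-corrected) protein distance.

    Returns ``(p_dist, d_prot)``; ``d_prot`` is ``None`` at saturation
    (p_dist >= 1 under the Poisson correction).
    """
    if pair.n_codons == 0:
        raise ValueError("empty pair")
    if correction not in ("none", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    diffs = sum(1 for a, b in zip(pair.protein_a, pair.protein_b) if a != b)
    p = diffs / pair.n_codons
    if correction == "none":
        return p, p
    if p >= 1.0:
        return p, None
    return p, -math.log(1.0 - p)


# ---------------------------------------------------------------------------
# NG86-style site and difference counting

def _partition_key(partition: DayhoffPartition) -> tuple[str, ...]:
    return partition.classes


@lru_cache(maxsize=None)
def _codon_sites(codon: str, classes: tuple[str, ...]) -> tuple[float, float, float]:
    """(synonymous, radical, conservative) site fractions for one sense codon.

    At each of the three positions the three single-nucleotide changes are
    considered; changes producing a stop codon are excluded and the
    remaining changes share the position's one site equally, so every
    codon contributes exactly 3 sites and N = radical + conservative.
    """
    partition = DayhoffPartition(classes)
    aa0 = CODON_AA[codon]
    s = r = c = 0.0
    for pos in range(3):
        alts = []
        for nt in _NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if CODON_AA[alt] != "*":
                alts.append(alt)
        m = len(alts)
        for alt in alts:
            aa1 = CODON_AA[alt]
            if aa1 == aa0:
                s += 1.0 / m
            elif partition.is_radical(aa0, aa1):
                r += 1.0 / m
            else:
                c += 1.0 / m
    return s, r, c


@lru_cache(maxsize=None)
def _pair_differences(
    codon_a: str, codon_b: str, classes: tuple[str, ...]
) -> tuple[float, float, float]:
    """(synonymous, radical, conservative) differences for one codon column.

    Differences at k positions are averaged over all k! minimal mutational
    pathways with equal weight; pathways passing through a stop codon are
    excluded. In the degenerate case where every pathway is blocked, all
    pathways are used and any step into or out of a stop is scored as a
    radical nonsynonymous change.
    """
    partition = DayhoffPartition(classes)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0, 0.0

    def walk(order: Sequence[int], allow_stop: bool) -> tuple[float, float, float] | None:
        cur = codon_a
        s = r = c = 0.0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            aa0, aa1 = CODON_AA[cur], CODON_AA[nxt]
            if "*" in (aa0, aa1):
                if not allow_stop:
                    return None
                r += 1.0  # stop-touching step scored radical nonsynonymous
            elif aa0 == aa1:
                s += 1.0
            elif partition.is_radical(aa0, aa1):
                r += 1.0
            else:
                c += 1.0
            cur = nxt
        return s, r, c

    results = [res for order in itertools.permutations(diff_pos) if (res := walk(order, False))]
    if not results:
        results = [walk(order, True) for order in itertools.permutations(diff_pos)]
    n = len(results)
    return (
        sum(x[0] for x in results) / n,
        sum(x[1] for x in results) / n,
        sum(x[2] for x in results) / n,
    )


def _jc_correct(p: float) -> float | None:
    """Jukes–Cantor multiple-hit correction; None at saturation (p >= 3/4)."""
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _rate_ratio(num: float | None, den: float | None) -> float | None:
    """num/den with explicit undefined flags.

    None when the denominator rate is 0 or when either rate is saturated —
    except that a saturated denominator with a numerator of exactly 0
    still has a well-defined ratio of 0 (the denominator is merely large).
    """
    if num is None:
        return None
    if den is None:
        return 0.0 if num == 0.0 else None
    if den == 0.0:
        return None
    return num / den


def _count_pair(
    pair: CodonAlignedPair, partition: DayhoffPartition
) -> tuple[float, float, float, float, float, float, float]:
    """Accumulate (S_sites, N_R, N_C, S_diff, O_R, O_C, N_sites) over the pair."""
    key = _partition_key(partition)
    S_sites = N_R = N_C = 0.0
    S_diff = O_R = O_C = 0.0
    for ca, cb in zip(pair.codons_a, pair.codons_b):
        sa, ra, cca = _codon_sites(ca, key)
        sb, rb, ccb = _codon_sites(cb, key)
        S_sites += (sa + sb) / 2.0
        N_R += (ra + rb) / 2.0
        N_C += (cca + ccb) / 2.0
        ds, dr, dc = _pair_differences(ca, cb, key)
        S_diff += ds
        O_R += dr
        O_C += dc
    return S_sites, N_R, N_C, S_diff, O_R, O_C, N_R + N_C


def estimate_dn_ds(
    pair: CodonAlignedPair, partition: DayhoffPartition | None = None
) -> tuple[float | None, float | None, float | None, float, float]:
    """NG86-style (dN, dS, omega, N_sites, S_sites) with Jukes–Cantor correction.

    ``omega`` is None when dS is zero or either rate is saturated; a
    saturated proportion (p >= 3/4) makes the affected rate None.
    """
    if pair.n_codons == 0:
        raise ValueError("empty pair")
    partition = partition or DayhoffPartition()
    S_sites, _, _, S_diff, O_R, O_C, N_sites = _count_pair(pair, partition)
    N_diff = O_R + O_C
    pN = N_diff / N_sites if N_sites > 0 else 0.0
    pS = S_diff / S_sites if S_sites > 0 else 0.0
    dN = _jc_correct(pN)
    dS = _jc_correct(pS)
    return dN, dS, _rate_ratio(dN, dS), N_sites, S_sites


def estimate_dr_dc(
    pair: CodonAlignedPair, partition: DayhoffPartition | None = None
) -> tuple[float | None, float | None, float | None, float, float, float, float]:
    """Zhang-style (dR, dC, dR/dC, N_R, N_C, O_R, O_C).

    Nonsynonymous sites are split fractionally into radical and
    conservative subsets by the Dayhoff classifier; observed nonsynonymous
    differences are classified with the same pathway averaging as
    :func:`estimate_dn_ds`; each proportion is Jukes–Cantor corrected.
    """
    if pair.n_codons == 0:
        raise ValueError("empty pair")
    partition = partition or DayhoffPartition()
    _, N_R, N_C, _, O_R, O_C, _ = _count_pair(pair, partition)
    pR = O_R / N_R if N_R > 0 else 0.0
    pC = O_C / N_C if N_C > 0 else 0.0
    dR = _jc_correct(pR)
    dC = _jc_correct(pC)
    return dR, dC, _rate_ratio(dR, dC), N_R, N_C, O_R, O_C


# ---------------------------------------------------------------------------
# region / charged-residue profiling


def region_and_charge_profile(
    pair: CodonAlignedPair,
    regions: RegionAnnotation,
    partition: DayhoffPartition | None = None,
    charged_set: frozenset[str] | set[str] = DEFAULT_CHARGED_SET,
) -> tuple[dict[str, dict[str, int]], int, int]:
    """Tally radical/conservative changes per topological region of sequence A.

    Each amino-acid-differing column is assigned the region of its ungapped
    position in the reference (first) sequence. A substitution counts
    toward ``charged_subs`` when either residue of the column lies in
    ``charged_set``.
    """
    partition = partition or DayhoffPartition()
    charged_set = frozenset(charged_set)
    ungapped_len = (max(pair.positions_a) + 1) if pair.positions_a else 0
    if len(regions.labels) < ungapped_len:
        raise ValueError(
            f"annotation length {len(regions.labels)} shorter than reference "
            f"protein length {ungapped_len}"
        )
    tallies: dict[str, dict[str, int]] = {
        label: {"radical": 0, "conservative": 0} for label in REGION_LABELS + ("unassigned",)
    }
    charged_total = charged_in_tm = 0
    prot_a, prot_b = pair.protein_a, pair.protein_b
    for i, (aa, ab) in enumerate(zip(prot_a, prot_b)):
        if aa == ab:
            continue
        label = regions.labels[pair.positions_a[i]]
        kind = "radical" if partition.is_radical(aa, ab) else "conservative"
        tallies[label][kind] += 1
        if aa in charged_set or ab in charged_set:
            charged_total += 1
            if label == TM:
                charged_in_tm += 1
    return tallies, charged_total, charged_in_tm


# ---------------------------------------------------------------------------
# one-stop analysis


def analyze_pair(
    pair: CodonAlignedPair,
    regions: RegionAnnotation | None = None,
    partition: DayhoffPartition | None = None,
    charged_set: frozenset[str] | set[str] = DEFAULT_CHARGED_SET,
    correction: str = "poisson",
) -> DivergenceEstimates:
    """Compute every divergence statistic for one pair in a single pass."""
    partition = partition or DayhoffPartition()
    p_dist, d_prot = protein_distance(pair, correction)
    S_sites, N_R, N_C, S_diff, O_R, O_C, N_sites = _count_pair(pair, partition)
    N_diff = O_R + O_C
    pN = N_diff / N_sites if N_sites > 0 else 0.0
    pS = S_diff / S_sites if S_sites > 0 else 0.0
    pR = O_R / N_R if N_R > 0 else 0.0
    pC = O_C / N_C if N_C > 0 else 0.0
    dN, dS, dR, dC = map(_jc_correct, (pN, pS, pR, pC))
    omega = _rate_ratio(dN, dS)
    dRdC = _rate_ratio(dR, dC)
    est = DivergenceEstimates(
        gene_id_a=pair.gene_id_a,
        gene_id_b=pair.gene_id_b,
        n_codons=pair.n_codons,
        p_dist=p_dist,
        d_prot=d_prot,
        d_prot_model=correction,
        dN=dN,
        dS=dS,
        omega=omega,
        N_sites=N_sites,
        S_sites=S_sites,
        N_diff=N_diff,
        S_diff=S_diff,
        N_R=N_R,
        N_C=N_C,
        O_R=O_R,
        O_C=O_C,
        dR=dR,
        dC=dC,
        dRdC=dRdC,
    )
    if regions is not None:
        tallies, charged, charged_tm = region_and_charge_profile(
            pair, regions, partition, charged_set
        )
        est.region_tallies = tallies
        est.charged_subs_total = charged
        est.charged_subs_in_TM = charged_tm
    return est
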