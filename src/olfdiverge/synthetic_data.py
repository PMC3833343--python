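"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the *shapes* of the study's data — codon-aligned
ortholog pairs, bootstrap-supported gene trees of two species, single
replicate read-count tables, fixed-difference variant sets and sparse
receptor-tuning response matrices — with deliberately simple stochastic
models (uniform sense-codon usage, Poisson counts, supports fixed at
100). They test the pipeline's logic, not biological realism; every
dataset is a pure function of its seed and ships the truth needed to
score the stage that consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .divergence import (
    CODON_AA,
    SENSE_CODONS,
    CodonAlignedPair,
    DayhoffPartition,
)
from .orthogroups import GeneTree

__all__ = [
    "SimulationConfig",
    "simulate_codon_pair",
    "simulate_counts",
    "simulate_gene_trees",
    "simulate_response_matrix",
    "simulate_variants",
]

_NUCS = "ACGT"

# default odorant chemical classes, loosely mirroring a deorphanization panel
_CLASSES = ("ester", "alcohol", "aromatic", "ketone", "acid", "indole")


@dataclass
class SimulationConfig:
    """Knobs for all five generators; the defaults define the test conditions.

    Divergence: ortholog pairs of ``n_codons`` codons, evolved at rate
    ``subs_per_codon`` expected mutation events per codon per lineage with
    nonsynonymous acceptance probability ``omega_true`` and planted
    radical fraction ``radical_bias``.

    Expression: ``n_genes`` genes, a ``de_fraction`` of which differ by
    ``effect_log2fc`` between species, Poisson counts around
    ``mean_depth`` reads per gene, equal library sizes.

    Orthogroups: ``n_ogs`` ancestral genes, per-OG single gain/loss
    probabilities ``p_gain``/``p_loss``, supports fixed at 100.

    Receptivity: ``n_receptors`` x ``n_odorants`` sparse tuning matrix with
    strong responses in ``response_scale`` spikes/s above the 100 spikes/s
    retention threshold for a ``tuning_sparsity`` fraction of odorants per
    receptor; one planted species-biased chemical class.

    Pseudoref: a random reference of ``ref_length`` bp with ``n_variants``
    SNVs whose depths/qualities span the filter boundaries.
    """

    seed: int = 0
    # divergence
    n_codons: int = 3000
    omega_true: float = 0.5
    radical_bias: float = 0.5
    subs_per_codon: float = 0.15
    # expression
    n_genes: int = 2000
    de_fraction: float = 0.5
    effect_log2fc: float = 2.0
    mean_depth: float = 200.0
    gene_length: int = 1000
    library_size: int = 1_000_000
    # orthogroups
    n_ogs: int = 250
    p_gain: float = 0.03
    p_loss: float = 0.02
    # receptivity
    n_receptors: int = 20
    n_odorants: int = 24
    tuning_sparsity: float = 0.25
    response_scale: float = 150.0
    bias_factor: float = 3.0
    # pseudoref
    n_variants: int = 60
    ref_length: int = 5000
    depth_range: tuple[int, int] = (2, 12)
    quality_range: tuple[float, float] = (30.0, 90.0)
    species_a: str = "gambiae"
    species_b: str = "quadriannulatus"

    def __post_init__(self) -> None:
        for name in ("radical_bias", "de_fraction", "tuning_sparsity", "p_gain", "p_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.omega_true < 0:
            raise ValueError("omega_true must be non-negative")

    def rng(self, *salt: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, *salt)))


# ---------------------------------------------------------------------------
# codon pairs


def _nonsyn_neighbors(codon: str, radical: bool, partition: DayhoffPartition) -> list[str]:
    """Single-nucleotide nonsynonymous neighbours of the requested class."""
    aa0 = CODON_AA[codon]
    out = []
    for pos in range(3):
        for nt in _NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            aa1 = CODON_AA[alt]
            if aa1 in ("*", aa0):
                continue
            if partition.is_radical(aa0, aa1) == radical:
                out.append(alt)
    return out


def _evolve(
    codons: list[str],
    rng: np.random.Generator,
    omega: float,
    radical_bias: float,
    subs_per_codon: float,
    partition: DayhoffPartition,
    truth: dict,
) -> list[str]:
    out = list(codons)
    n_events = rng.poisson(subs_per_codon, size=len(out))
    for i, k in enumerate(n_events):
        for _ in range(k):
            codon = out[i]
            pos = rng.integers(3)
            nt = _NUCS[rng.integers(4)]
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            aa0, aa1 = CODON_AA[codon], CODON_AA[alt]
            if aa1 == "*":
                continue  # nonsense mutations rejected
            if aa1 == aa0:
                out[i] = alt
                truth["syn_subs"] += 1
                continue
            if rng.random() >= omega:
                continue  # purifying selection rejects the replacement
            # steer the accepted replacement toward the planted radical bias
            want_radical = rng.random() < radical_bias
            if partition.is_radical(aa0, aa1) != want_radical:
                candidates = _nonsyn_neighbors(codon, want_radical, partition)
                if candidates:
                    alt = candidates[rng.integers(len(candidates))]
                    aa1 = CODON_AA[alt]
            out[i] = alt
            if partition.is_radical(aa0, aa1):
                truth["radical_subs"] += 1
            else:
                truth["conservative_subs"] += 1
    return out


def simulate_codon_pair(config: SimulationConfig) -> tuple[CodonAlignedPair, dict]:
    """Evolve one ortholog pair from a common ancestor.

    Mutation proposals are neutral (uniform position and nucleotide);
    synonymous proposals always fix, nonsynonymous ones with probability
    ``omega_true``, and accepted replacements are radical with probability
    ``radical_bias`` (re-drawn among same-codon neighbours of the desired
    class where one exists). No gaps are introduced.
    """
    rng = config.rng(1)
    partition = DayhoffPartition()
    ancestor = [SENSE_CODONS[j] for j in rng.integers(len(SENSE_CODONS), size=config.n_codons)]
    truth: dict = {
        "omega_true": config.omega_true,
        "radical_bias": config.radical_bias,
        "syn_subs": 0,
        "radical_subs": 0,
        "conservative_subs": 0,
    }
    seq_a = _evolve(ancestor, rng, config.omega_true, config.radical_bias,
                    config.subs_per_codon, partition, truth)
    seq_b = _evolve(ancestor, rng, config.omega_true, config.radical_bias,
                    config.subs_per_codon, partition, truth)
    pair = CodonAlignedPair(
        gene_id_a="simA",
        gene_id_b="simB",
        codons_a=tuple(seq_a),
        codons_b=tuple(seq_b),
        positions_a=tuple(range(config.n_codons)),
        positions_b=tuple(range(config.n_codons)),
        species_a=config.species_a,
        species_b=config.species_b,
    )
    return pair, truth


# ---------------------------------------------------------------------------
# count tables


def simulate_counts(config: SimulationConfig):
    """Poisson count table with a planted differentially expressed fraction.

    Per-gene base rates are drawn lognormally around ``mean_depth``; a
    ``de_fraction`` of genes has its species-b rate shifted by
    ``±effect_log2fc`` (sign random). Returns (CountTable, truth frame).
    """
    from .expression import CountTable

    rng = config.rng(2)
    n = config.n_genes
    base = rng.lognormal(mean=np.log(config.mean_depth), sigma=0.6, size=n)
    is_de = rng.random(n) < config.de_fraction
    sign = rng.choice([-1.0, 1.0], size=n)
    true_lfc = np.where(is_de, sign * config.effect_log2fc, 0.0)
    rate_a = base
    rate_b = base * 2.0 ** true_lfc
    genes = [f"gene{i:05d}" for i in range(n)]
    frame = pd.DataFrame(
        {
            "count_a": rng.poisson(rate_a),
            "count_b": rng.poisson(rate_b),
            "length": config.gene_length,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    truth = pd.DataFrame(
        {"is_de": is_de, "true_log2fc": true_lfc},
        index=pd.Index(genes, name="gene_id"),
    )
    table = CountTable(frame=frame, lib_a=config.library_size, lib_b=config.library_size)
    return table, truth


# ---------------------------------------------------------------------------
# gene trees


def simulate_gene_trees(config: SimulationConfig) -> tuple[list[GeneTree], pd.DataFrame]:
    """A forest of per-OG gene trees with recorded gain/loss events.

    Each of ``n_ogs`` ancestral genes independently gains one extra copy
    in a random species with probability ``p_gain`` and is lost from a
    random species with probability ``p_loss`` (a loss never strikes the
    species that just gained, keeping losses within {0,1} per species).
    All supports are written as 100.
    """
    rng = config.rng(3)
    sp_a, sp_b = config.species_a, config.species_b
    trees: list[GeneTree] = []
    rows = []
    for og in range(config.n_ogs):
        counts = {sp_a: 1, sp_b: 1}
        gains = {sp_a: 0, sp_b: 0}
        losses = {sp_a: 0, sp_b: 0}
        gained_sp = None
        if rng.random() < config.p_gain:
            gained_sp = sp_a if rng.random() < 0.5 else sp_b
            counts[gained_sp] += 1
            gains[gained_sp] += 1
        if rng.random() < config.p_loss:
            candidates = [s for s in (sp_a, sp_b) if s != gained_sp]
            lost_sp = candidates[int(rng.integers(len(candidates)))]
            counts[lost_sp] -= 1
            losses[lost_sp] += 1
        members = {
            sp: [f"{'G' if sp == sp_a else 'Q'}{og:04d}_{i}" for i in range(counts[sp])]
            for sp in (sp_a, sp_b)
        }
        leaves_a, leaves_b = members[sp_a], members[sp_b]
        if not leaves_a and not leaves_b:
            continue  # the gene vanished entirely; no tree to emit
        sub_a = f"({','.join(leaves_a)})100" if len(leaves_a) > 1 else "".join(leaves_a)
        sub_b = f"({','.join(leaves_b)})100" if len(leaves_b) > 1 else "".join(leaves_b)
        parts = [p for p in (sub_a, sub_b) if p]
        newick = f"({','.join(parts)})100;" if len(parts) == 2 else f"{parts[0]};"
        species_map = {g: sp for sp in (sp_a, sp_b) for g in members[sp]}
        trees.append(GeneTree(newick=newick, species_map=species_map))
        rows.append(
            {
                "og": og,
                "members_a": ",".join(sorted(leaves_a)),
                "members_b": ",".join(sorted(leaves_b)),
                "gains_a": gains[sp_a],
                "gains_b": gains[sp_b],
                "losses_a": losses[sp_a],
                "losses_b": losses[sp_b],
            }
        )
    return trees, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# response matrices


def simulate_response_matrix(config: SimulationConfig):
    """Sparse receptor tuning matrix plus paired species RPKM vectors.

    Receptors are split into specialists for one planted chemical class
    (the first of the class cycle, esters) and generalists for the rest.
    Strong responses (>= 100 spikes/s) cover a ``tuning_sparsity``
    fraction of each receptor's odorants; remaining cells are weak or
    mildly inhibitory. The paired RPKM table up-weights specialist
    receptors in species a by ``bias_factor`` and generalists in species
    b by a milder factor, planting an ester-class receptivity bias toward
    species a. Returns (matrix, metadata, truth dict with the RPKM table).
    """
    rng = config.rng(4)
    receptors = [f"Or{i + 1}" for i in range(config.n_receptors)]
    odorants = [f"odor{j:02d}" for j in range(config.n_odorants)]
    classes = [_CLASSES[j % len(_CLASSES)] for j in range(config.n_odorants)]
    biased_class = _CLASSES[0]
    meta = pd.DataFrame(
        {
            "chemical_class": classes,
            "human_associated": [cls in ("ester", "indole", "acid") for cls in classes],
        },
        index=pd.Index(odorants, name="odorant"),
    )
    biased_odorants = [o for o, cls in zip(odorants, classes) if cls == biased_class]
    other_odorants = [o for o in odorants if o not in biased_odorants]
    n_specialists = max(1, config.n_receptors // 3) if config.tuning_sparsity > 0 else 0

    matrix = pd.DataFrame(
        rng.uniform(-30.0, 30.0, size=(config.n_receptors, config.n_odorants)),
        index=pd.Index(receptors, name="receptor"),
        columns=pd.Index(odorants, name="odorant"),
    )
    k = int(round(config.tuning_sparsity * config.n_odorants))
    for i, rec in enumerate(receptors):
        if k == 0:
            continue
        pool = biased_odorants if i < n_specialists else other_odorants
        if not pool:
            pool = odorants
        chosen = rng.choice(pool, size=min(k, len(pool)), replace=False)
        matrix.loc[rec, chosen] = 100.0 + rng.uniform(0.0, config.response_scale, size=len(chosen))

    base = rng.uniform(20.0, 60.0, size=config.n_receptors)
    rpkm_a = base.copy()
    rpkm_b = base.copy()
    # specialists up-weighted in species a, generalists firmly in species b,
    # so the planted class lands outside the 10% band on the a side and the
    # rest on the b side
    rpkm_a[:n_specialists] *= config.bias_factor
    rpkm_b[n_specialists:] *= rng.uniform(1.2, 1.6, size=config.n_receptors - n_specialists)
    rpkm = pd.DataFrame(
        {config.species_a: rpkm_a, config.species_b: rpkm_b},
        index=pd.Index(receptors, name="receptor"),
    )
    truth = {
        "biased_class": biased_class,
        "biased_species": config.species_a,
        "specialists": receptors[:n_specialists],
        "rpkm": rpkm,
    }
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# variants


def simulate_variants(config: SimulationConfig):
    """Random reference plus SNVs spanning the depth/quality filter bounds.

    Depths are uniform over ``depth_range`` and qualities over
    ``quality_range`` (both spanning the depth-5 / quality-60 defaults);
    one in ten records is an indel, which the substitution step must skip.
    Truth lists the sites that a correct filter substitutes.
    """
    rng = config.rng(5)
    seq = "".join(_NUCS[j] for j in rng.integers(4, size=config.ref_length))
    reference = {"chr1": seq}
    positions = rng.choice(np.arange(1, config.ref_length + 1),
                           size=config.n_variants, replace=False)
    positions.sort()
    variants = []
    truth_rows = []
    from .pseudoref import VariantRecord

    for i, pos in enumerate(positions):
        ref = seq[pos - 1]
        depth = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
        quality = float(rng.uniform(*config.quality_range))
        is_indel = i % 10 == 9
        if is_indel:
            variants.append(
                VariantRecord(chrom="chr1", pos=int(pos), ref_allele=ref,
                              alt_alleles=(ref + "A",), depth=depth, quality=quality)
            )
            truth_rows.append({"pos": int(pos), "substituted": False, "alt": None,
                               "indel": True})
            continue
        alts = [nt for nt in _NUCS if nt != ref]
        n_alts = int(rng.integers(1, 3))
        chosen = list(rng.choice(alts, size=n_alts, replace=False))
        counts = list(rng.integers(1, 20, size=n_alts))
        best = max(counts)
        expected_alt = min(a for a, n in zip(chosen, counts) if n == best)
        passing = depth >= 5 and quality >= 60.0
        variants.append(
            VariantRecord(chrom="chr1", pos=int(pos), ref_allele=ref,
                          alt_alleles=tuple(chosen), depth=depth, quality=quality,
                          allele_counts=tuple(int(c) for c in counts))
        )
        truth_rows.append({"pos": int(pos), "substituted": passing,
                           "alt": expected_alt if passing else None, "indel": False})
    return reference, variants, pd.DataFrame(truth_rows)


def write_variants_vcf(variants, path) -> None:
    """Serialize simulated variants as an uncompressed VCF with DP and AD."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write("##contig=<ID=chr1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for v in variants:
            ad = ",".join(["0"] + [str(c) for c in v.allele_counts]) if v.allele_counts else "."
            fmt = f"GT:AD\t1/1:{ad}" if v.allele_counts else "GT\t1/1"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{','.join(v.alt_alleles)}"
                f"\t{v.quality:.1f}\tPASS\tDP={v.depth}\t{fmt}\n"
            )
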