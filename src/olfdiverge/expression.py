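"""Abundance quantification and single-replicate differential expression.

Implements RPKM normalisation, a GFOLD-style "reliable" log2 fold change
for unreplicated RNAseq (a conservative posterior bound: the value is the
credibility-level quantile of the posterior log2 ratio nearest to zero,
clamped to zero when the interval straddles it), Spearman rank-order
conservation of family expression, and the dN/dS-quartile contrast of
transcript enrichment.

The posterior model is Poisson counts with an uninformative Gamma prior:
the expression rate of a gene with count k in a library of size L has
posterior Gamma(k + 1) / L. Quantiles of the log2 rate ratio are taken by
Monte Carlo with a fixed seed, making every result reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountTable",
    "FoldChangeResult",
    "QuartileContrast",
    "compute_rpkm",
    "reliable_log2_fold",
    "fold_change_table",
    "rank_correlation",
    "quartile_contrast",
]


@dataclass
class CountTable:
    """Per-gene read counts for two single-replicate samples.

    ``frame`` columns: count_a, count_b (integers) and length (bp);
    indexed by gene id. Library sizes are total mapped reads per sample.
    """

    frame: pd.DataFrame
    lib_a: int
    lib_b: int

    def __post_init__(self) -> None:
        required = {"count_a", "count_b", "length"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"count table missing columns {sorted(missing)}")
        if self.lib_a <= 0 or self.lib_b <= 0:
            raise ValueError("library sizes must be positive")
        if (self.frame[["count_a", "count_b"]] < 0).any().any():
            raise ValueError("negative read counts")
        if (self.frame["length"] <= 0).any():
            raise ValueError("non-positive gene lengths")

    @classmethod
    def from_tsv(cls, path, lib_a: int, lib_b: int) -> "CountTable":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame=frame, lib_a=lib_a, lib_b=lib_b)


@dataclass
class FoldChangeResult:
    gene_id: str
    raw_log2fc: float | None  # None when either normalised abundance is 0
    gfold: float
    significant: bool
    c: float


@dataclass
class QuartileContrast:
    """|gfold| distribution contrasted across dN/dS quartiles."""

    table: pd.DataFrame  # per-quartile n, median, variance
    q1_vs_rest_stat: float
    q1_vs_rest_p: float
    pairwise: pd.DataFrame  # rank-sum statistic and p for each quartile pair
    degenerate: bool = False


def compute_rpkm(table: CountTable, detect_rpkm_min: float = 0.0) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, per gene and sample.

    RPKM = 1e9 * count / (library_size * gene_length). A gene is flagged
    detectable in a sample when its count is positive (optionally also
    requiring RPKM above ``detect_rpkm_min``).
    """
    f = table.frame
    out = pd.DataFrame(index=f.index)
    for s, lib in (("a", table.lib_a), ("b", table.lib_b)):
        rpkm = 1e9 * f[f"count_{s}"] / (lib * f["length"])
        out[f"rpkm_{s}"] = rpkm
        out[f"detectable_{s}"] = (f[f"count_{s}"] > 0) & (rpkm >= detect_rpkm_min)
    return out


def reliable_log2_fold(
    count_a: int,
    count_b: int,
    lib_a: int,
    lib_b: int,
    c: float = 0.99,
    draws: int = 100_000,
    seed: int = 0,
    gene_id: str = "",
) -> FoldChangeResult:
    """Signed reliable log2 fold change of sample b relative to sample a.

    Posterior rates are Gamma(count + 1)/lib; z = log2(rate_b / rate_a).
    With q_lo, q_hi the (1 - c) and c Monte-Carlo quantiles of z, the
    value is q_lo if q_lo > 0, q_hi if q_hi < 0, else 0 (not significant).
    """
    if count_a < 0 or count_b < 0 or count_a != int(count_a) or count_b != int(count_b):
        raise ValueError("counts must be non-negative integers")
    if not 0.5 < c < 1.0:
        raise ValueError(f"credibility level must lie in (0.5, 1), got {c}")
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    rng = np.random.default_rng(seed)
    rate_a = rng.gamma(count_a + 1, size=draws) / lib_a
    rate_b = rng.gamma(count_b + 1, size=draws) / lib_b
    z = np.log2(rate_b) - np.log2(rate_a)
    q_lo, q_hi = np.quantile(z, [1.0 - c, c])
    if q_lo > 0:
        gfold = float(q_lo)
    elif q_hi < 0:
        gfold = float(q_hi)
    else:
        gfold = 0.0
    raw = None
    if count_a > 0 and count_b > 0:
        raw = math.log2((count_b / lib_b) / (count_a / lib_a))
    return FoldChangeResult(
        gene_id=gene_id, raw_log2fc=raw, gfold=gfold, significant=gfold != 0.0, c=c
    )


def fold_change_table(
    table: CountTable,
    c: float = 0.99,
    draws: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene RPKM, raw log2 fold change and reliable fold change.

    Each gene gets an independent substream of the seed so results do not
    depend on gene order.
    """
    abund = compute_rpkm(table)
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(len(table.frame))
    for (gene_id, rec), ss in zip(table.frame.iterrows(), seeds):
        res = reliable_log2_fold(
            int(rec["count_a"]),
            int(rec["count_b"]),
            table.lib_a,
            table.lib_b,
            c=c,
            draws=draws,
            seed=ss,
            gene_id=str(gene_id),
        )
        rows.append(
            {
                "gene_id": gene_id,
                "raw_log2fc": res.raw_log2fc,
                "gfold": res.gfold,
                "significant": res.significant,
            }
        )
    fc = pd.DataFrame(rows).set_index("gene_id")
    return abund.join(fc)


def rank_correlation(abund: pd.DataFrame, gene_subset: list[str] | None = None) -> float:
    """Spearman rank correlation of abundances between species for a family.

    Only genes detectable in both samples enter; ties are mid-ranked.
    """
    sub = abund.loc[gene_subset] if gene_subset is not None else abund
    sub = sub[sub["detectable_a"] & sub["detectable_b"]]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 genes detectable in both species, got {len(sub)}")
    rho, _ = stats.spearmanr(sub["rpkm_a"], sub["rpkm_b"])
    return float(rho)


def quartile_contrast(
    omega_by_gene: pd.Series, gfold_by_gene: pd.Series
) -> QuartileContrast:
    """Contrast |gfold| across quartiles of dN/dS.

    Genes are split at the quartiles of omega (Q1 = most conserved);
    reports per-quartile median and variance of |gfold|, a Q1-vs-rest
    Wilcoxon rank-sum test and all pairwise rank-sum tests.
    """
    shared = omega_by_gene.index.intersection(gfold_by_gene.index)
    if len(shared) < 8:
        raise ValueError(f"need >= 8 shared genes, got {len(shared)}")
    omega = omega_by_gene.loc[shared].astype(float)
    absg = gfold_by_gene.loc[shared].abs().astype(float)
    if omega.nunique() == 1:
        return QuartileContrast(
            table=pd.DataFrame(),
            q1_vs_rest_stat=float("nan"),
            q1_vs_rest_p=float("nan"),
            pairwise=pd.DataFrame(),
            degenerate=True,
        )
    quart = pd.qcut(omega.rank(method="first"), 4, labels=["Q1", "Q2", "Q3", "Q4"])
    table = (
        pd.DataFrame({"quartile": quart, "abs_gfold": absg})
        .groupby("quartile", observed=True)["abs_gfold"]
        .agg(n="size", median="median", variance="var")
    )
    q1 = absg[quart == "Q1"]
    rest = absg[quart != "Q1"]
    stat, p = stats.ranksums(q1, rest)
    pairs = []
    labels = ["Q1", "Q2", "Q3", "Q4"]
    for i in range(4):
        for j in range(i + 1, 4):
            x, y = absg[quart == labels[i]], absg[quart == labels[j]]
            s, pv = stats.ranksums(x, y)
            pairs.append({"pair": f"{labels[i]}-{labels[j]}", "stat": s, "p": pv})
    return QuartileContrast(
        table=table,
        q1_vs_rest_stat=float(stat),
        q1_vs_rest_p=float(p),
        pairwise=pd.DataFrame(pairs),
    )
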