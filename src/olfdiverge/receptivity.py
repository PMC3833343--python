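"""RPKM-weighted antennal odorant-receptivity model.

The whole antenna is treated as one chemosensory unit: the deorphanised
response of each odorant receptor (Δ spikes/s over baseline) to each
odorant is weighted by the receptor's transcript abundance (RPKM) in a
species and summed over receptors, giving a per-odorant "antennal
receptivity". Dividing the receptivity of one species by its sibling's
yields the interspecific receptivity change, which is banded (within 10%,
enriched in species 1, enriched in species 2) and tested per chemical
class for disproportionate representation with Fisher's exact test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "BAND_WITHIN",
    "BAND_SP1",
    "BAND_SP2",
    "filter_matrix",
    "compute_receptivity",
    "receptivity_change",
    "class_enrichment",
    "fisher_exact_two_sided",
    "map_orthologs",
]

BAND_WITHIN = "within_10pct"
BAND_SP1 = "gambiae_enriched"
BAND_SP2 = "quad_enriched"
BAND_UNDEFINED = "undefined"


def filter_matrix(matrix: pd.DataFrame, threshold: float = 100.0) -> pd.DataFrame:
    """Drop weakly responding receptors, then weakly activating odorants.

    A receptor (row) is kept when it elicits at least ``threshold``
    spikes/s over baseline for some odorant; odorant columns are then
    re-evaluated over the surviving receptors. Missing cells are ignored
    when taking maxima. The two-stage order (receptors first) is fixed.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    row_max = matrix.max(axis=1, skipna=True)
    keep_r = row_max >= threshold
    dropped_r = list(matrix.index[~keep_r.fillna(False)])
    out = matrix.loc[keep_r.fillna(False)]
    if out.empty:
        log.info("all %d receptors dropped by the %.0f spikes/s filter", len(matrix), threshold)
        return out.iloc[:, 0:0]
    col_max = out.max(axis=0, skipna=True)
    keep_o = col_max >= threshold
    dropped_o = list(out.columns[~keep_o.fillna(False)])
    if dropped_r or dropped_o:
        log.info("filter dropped receptors=%s odorants=%s", dropped_r, dropped_o)
    return out.loc[:, keep_o.fillna(False)]


def compute_receptivity(matrix: pd.DataFrame, rpkm: pd.Series) -> pd.Series:
    """Per-odorant antennal receptivity A(o) = sum_r RPKM(r) * max(resp, 0).

    Odor-induced decreases in spiking (negative responses) are treated as
    indeterminate and contribute zero; missing cells likewise (their count
    is logged). Every receptor in the matrix must have an RPKM weight.
    """
    missing = matrix.index.difference(rpkm.index)
    if len(missing):
        raise KeyError(f"no RPKM for receptors {list(missing)}")
    weights = rpkm.loc[matrix.index].astype(float)
    if (weights < 0).any():
        raise ValueError("negative RPKM weight")
    n_missing_cells = int(matrix.isna().sum().sum())
    if n_missing_cells:
        log.info("%d missing response cells treated as 0", n_missing_cells)
    clamped = matrix.clip(lower=0).fillna(0.0)
    return clamped.mul(weights, axis=0).sum(axis=0)


def receptivity_change(
    profile_1: pd.Series, profile_2: pd.Series, band_percent: float = 10.0
) -> pd.DataFrame:
    """Interspecific receptivity change per odorant, banded and sorted.

    ratio = A_1 / A_2; signed_percent = 100*(ratio - 1) for ratio >= 1,
    else -100*(1/ratio - 1), so enrichment in either species is on a
    symmetric percent scale. One-sided zeros give an infinite change in
    the non-zero species' direction (flagged ``one_sided``); odorants with
    zero receptivity in both species are flagged undefined and sorted last.
    """
    if set(profile_1.index) != set(profile_2.index):
        raise ValueError("profiles cover different odorant sets")
    rows = []
    for odorant in profile_1.index:
        a1, a2 = float(profile_1[odorant]), float(profile_2[odorant])
        if a1 == 0.0 and a2 == 0.0:
            rows.append(
                {"odorant": odorant, "ratio": math.nan, "signed_percent": math.nan,
                 "band": BAND_UNDEFINED, "one_sided": False}
            )
            continue
        one_sided = a1 == 0.0 or a2 == 0.0
        ratio = math.inf if a2 == 0.0 else a1 / a2
        if ratio >= 1.0:
            sp = 100.0 * (ratio - 1.0)
        elif ratio == 0.0:
            sp = -math.inf
        else:
            sp = -100.0 * (1.0 / ratio - 1.0)
        if abs(sp) <= band_percent:
            band = BAND_WITHIN
        elif sp > 0:
            band = BAND_SP1
        else:
            band = BAND_SP2
        rows.append(
            {"odorant": odorant, "ratio": ratio, "signed_percent": sp,
             "band": band, "one_sided": one_sided}
        )
    frame = pd.DataFrame(rows).set_index("odorant")
    defined = frame[frame["band"] != BAND_UNDEFINED].sort_values(
        "signed_percent", ascending=False
    )
    undefined = frame[frame["band"] == BAND_UNDEFINED]
    return pd.concat([defined, undefined])


def fisher_exact_two_sided(table: list[list[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test by exact hypergeometric enumeration.

    Returns (odds_ratio, p). With margins fixed, every table at least as
    extreme (point probability <= that of the observed table) contributes;
    probabilities are compared as exact rationals so knife-edge ties are
    handled without floating-point ambiguity.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return math.nan, 1.0
    # integer pmf numerators over the common denominator C(n, c1):
    # comparisons and the tail sum are exact, floats enter only at the end
    lo, hi = max(0, c1 - r2), min(r1, c1)
    numerators = {x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)}
    obs = numerators[a]
    tail = sum(v for v in numerators.values() if v <= obs)
    p = float(Fraction(tail, math.comb(n, c1)))
    odds = math.inf if b * c == 0 and a * d > 0 else (
        math.nan if b * c == 0 else a * d / (b * c)
    )
    return odds, min(p, 1.0)


def class_enrichment(
    changes: pd.DataFrame,
    meta: pd.DataFrame,
    grouping: str = "chemical_class",
    min_abs_percent: float | None = None,
) -> pd.DataFrame:
    """Per-group Fisher tests of band bias among enriched odorants.

    For each level of ``grouping`` (a column of ``meta``: chemical_class
    or human_associated) a 2x2 table of (in-group vs out-group) x
    (species-1-enriched vs species-2-enriched) is tested; within-band
    odorants do not enter. ``min_abs_percent`` optionally restricts to
    odorants whose absolute signed percent exceeds it. Groups with an
    empty in- or out-group stratum are flagged ``untestable``.
    """
    missing = changes.index.difference(meta.index)
    if len(missing):
        raise KeyError(f"odorants without metadata: {list(missing)}")
    if grouping not in meta.columns:
        raise KeyError(f"metadata has no column {grouping!r}")
    sub = changes[changes["band"].isin([BAND_SP1, BAND_SP2])]
    if min_abs_percent is not None:
        sub = sub[sub["signed_percent"].abs() > min_abs_percent]
    labels = meta.loc[sub.index, grouping]
    rows = []
    for level in sorted(labels.unique(), key=str):
        in_group = labels == level
        a = int(((sub["band"] == BAND_SP1) & in_group).sum())
        b = int(((sub["band"] == BAND_SP2) & in_group).sum())
        c = int(((sub["band"] == BAND_SP1) & ~in_group).sum())
        d = int(((sub["band"] == BAND_SP2) & ~in_group).sum())
        if a + b == 0 or c + d == 0:
            rows.append(
                {"group": level, "table": [[a, b], [c, d]], "odds_ratio": math.nan,
                 "p": math.nan, "untestable": True}
            )
            continue
        odds, p = fisher_exact_two_sided([[a, b], [c, d]])
        rows.append(
            {"group": level, "table": [[a, b], [c, d]], "odds_ratio": odds,
             "p": p, "untestable": False}
        )
    return pd.DataFrame(rows)


def map_orthologs(rpkm: pd.Series, ortholog_map: pd.Series) -> pd.Series:
    """Re-key a sibling species' RPKM vector onto reference receptor ids.

    ``ortholog_map`` maps reference receptor id -> sibling gene id. The
    receptivity model assumes functional conservation among interspecific
    OR orthologs, so each reference receptor's response profile is
    weighted by its ortholog's abundance in the sibling species.
    """
    out = {}
    for ref_id, other_id in ortholog_map.items():
        if other_id in rpkm.index:
            out[ref_id] = float(rpkm[other_id])
    return pd.Series(out, dtype=float)
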