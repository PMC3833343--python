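# olfdiverge

Comparative analysis of chemosensory gene divergence between two sibling
mosquito species — an anthropophilic species (*An. gambiae*-like, "species
g") and its zoophilic sibling (*An. quadriannulatus*-like, "species q").
The package asks how host preference can diverge when two genomes are
nearly identical: not by gene family turnover, but through sequence-level
divergence of orthologous receptors and quantitative shifts in their
antennal transcript abundance.

It provides, as a tested and reusable library with a CLI:

* **divergence** — codon-counting molecular-evolution statistics on
  aligned ortholog pairs: protein distance (p-distance, Poisson
  corrected), dN/dS by Nei–Gojobori-style pathway counting with
  Jukes–Cantor correction, radical-vs-conservative dR/dC with the Dayhoff
  residue classes {AGPST, DENQ, HKR, ILMV, FWY, C}, and substitution
  profiling stratified by membrane-topology regions (TM / inside /
  outside) with a configurable "charged residue" tally (default {E, N, Y}).
* **orthogroups** — orthologous-group delineation from bootstrap-supported
  gene trees of the two species (a supported clade representing one
  ancestral gene), with per-branch gain/loss bookkeeping
  (count = 1 + gains − losses).
* **expression** — RPKM normalisation and a GFOLD-style *reliable* log2
  fold change for single-replicate RNAseq: the Poisson–Gamma posterior
  quantile of the log2 rate ratio nearest zero, clamped to zero when the
  credible interval straddles it (gfold ≠ 0 ⇔ significant); Spearman
  rank-order conservation and dN/dS-quartile contrasts of |gfold|.
* **pseudoref** — pseudo-reference construction: fixed interspecific
  differences (SNVs with depth ≥ 5 and quality ≥ 60) substituted into the
  reference with each site's most frequent alternative allele, to remove
  cross-species read-mapping bias.
* **receptivity** — the antennal odorant-receptivity model: deorphanised
  receptor responses (Δspikes/s, filtered at 100 spikes/s) weighted by
  per-species receptor RPKM and summed per odorant,
  A_s(o) = Σ_r RPKM_s(r)·max(response(r,o), 0); the interspecific ratio
  ρ(o) = A_g(o)/A_q(o) expressed as a symmetric signed percent, banded at
  ±10%, and tested per chemical class with an exact two-sided Fisher test.
* **synthetic_data** — seeded generators for every input (codon pairs
  evolved at a chosen ω and radical bias, gene-tree forests with recorded
  gains/losses, Poisson count tables with planted effects,
  fixed-difference variant sets, sparse receptor-tuning matrices with a
  planted class bias), each shipping its ground truth.

## Worked example

Generate a synthetic ortholog pair evolved at ω = 0.5 and estimate its
divergence statistics:

```python
from olfdiverge.divergence import estimate_dn_ds, estimate_dr_dc
from olfdiverge.synthetic_data import SimulationConfig, simulate_codon_pair

pair, truth = simulate_codon_pair(SimulationConfig(seed=1, n_codons=3000,
                                                   omega_true=0.5))
dN, dS, omega, N_sites, S_sites = estimate_dn_ds(pair)
print(f"dN={dN:.4f} dS={dS:.4f} omega={omega:.3f}")
```

prints

```
dN=0.0366 dS=0.0618 omega=0.592
```

dN and dS are substitutions per nonsynonymous and synonymous site; their
ratio estimates the strength of selection (ω < 1: purifying; here the
single replicate scatters around the simulated truth of 0.5, and the
median over 50 replicates recovers it within a few percent).

The receptivity model on its worked toy — two receptors responding at 50
and 100 Δspikes/s to one odorant, RPKM weights (10, 0) in species g and
(5, 5) in species q:

```python
import pandas as pd
from olfdiverge.receptivity import compute_receptivity, receptivity_change

m = pd.DataFrame({"X": [50.0, 100.0]}, index=["Or1", "Or2"])
A_g = compute_receptivity(m, pd.Series({"Or1": 10.0, "Or2": 0.0}))
A_q = compute_receptivity(m, pd.Series({"Or1": 5.0, "Or2": 5.0}))
print(receptivity_change(A_g, A_q))
```

```
            ratio  signed_percent           band  one_sided
odorant
X        0.666667           -50.0  quad_enriched      False
```

Species q's antenna is 50% more receptive to odorant X: the ratio 2/3 on
a symmetric percent scale, outside the ±10% "unchanged" band.

The CLI mirrors the library: `olfdiverge simulate|divergence|orthogroups|
expression|pseudoref|receptivity|run` (see `olfdiverge --help`); `run`
drives the full pipeline from a YAML config and writes a report directory
of TSV/JSON tables with a provenance block.

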