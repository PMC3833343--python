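"""Orthologous-group delineation and gain/loss bookkeeping from gene trees.

An orthologous group (OG) is a highly supported clade of a two-species
gene tree that is consistent with a single gene in the species' most
recent common ancestor: either one gene per species (1:1), or k genes of
one species with at most one of the other (k-1 lineage-specific gains,
plus one loss when the other species is absent). Per-species counts always
reconstruct as 1 + gains - losses.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "GeneTree",
    "OrthologGroup",
    "RepertoireSummary",
    "delineate_orthogroups",
    "delineate_forest",
    "summarize_repertoire",
]


@dataclass
class GeneTree:
    """A (rooted) gene tree with bootstrap supports and a gene->species map."""

    newick: str
    species_map: dict[str, str]

    def to_dendropy(self) -> dendropy.Tree:
        tree = dendropy.Tree.get(
            data=self.newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        return tree


@dataclass
class OrthologGroup:
    """One ancestral gene and its descendants in the two extant species."""

    members_a: list[str]
    members_b: list[str]
    species_a: str
    species_b: str
    gains_a: int = 0
    gains_b: int = 0
    losses_a: int = 0
    losses_b: int = 0
    ancestral_copies: int = 1

    def validate(self) -> None:
        for members, gains, losses, label in (
            (self.members_a, self.gains_a, self.losses_a, self.species_a),
            (self.members_b, self.gains_b, self.losses_b, self.species_b),
        ):
            if losses not in (0, 1):
                raise ValueError(f"losses for {label} must be 0 or 1, got {losses}")
            if gains < 0:
                raise ValueError(f"negative gains for {label}")
            if len(members) != self.ancestral_copies + gains - losses:
                raise ValueError(
                    f"bookkeeping violated for {label}: {len(members)} members "
                    f"!= {self.ancestral_copies} + {gains} - {losses}"
                )

    def to_row(self) -> dict:
        return {
            "members_a": ",".join(sorted(self.members_a)),
            "members_b": ",".join(sorted(self.members_b)),
            "n_a": len(self.members_a),
            "n_b": len(self.members_b),
            "gains_a": self.gains_a,
            "gains_b": self.gains_b,
            "losses_a": self.losses_a,
            "losses_b": self.losses_b,
        }


@dataclass
class RepertoireSummary:
    """Figure-1-style per-family summary of counts, MRCA size and events."""

    families: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return self.families


def _node_support(node: dendropy.Node) -> float:
    """Bootstrap support of an internal node; unlabeled nodes (e.g. the
    root as written by most ML programs) are treated as fully supported."""
    label = node.label
    if label is None or label == "":
        return 100.0
    return float(label)


def _og_from_counts(
    genes_a: list[str], genes_b: list[str], species_a: str, species_b: str
) -> OrthologGroup:
    na, nb = len(genes_a), len(genes_b)
    og = OrthologGroup(
        members_a=sorted(genes_a),
        members_b=sorted(genes_b),
        species_a=species_a,
        species_b=species_b,
        gains_a=max(na - 1, 0),
        gains_b=max(nb - 1, 0),
        losses_a=1 if na == 0 else 0,
        losses_b=1 if nb == 0 else 0,
    )
    og.validate()
    return og


def delineate_orthogroups(
    tree: GeneTree,
    support_threshold: float = 90.0,
    midpoint_root: bool = False,
    species: tuple[str, str] | None = None,
) -> list[OrthologGroup]:
    """Partition a gene tree's leaves into orthologous groups.

    A clade qualifies as one OG when its support strictly exceeds
    ``support_threshold`` and its gene content is consistent with a single
    ancestral gene: min(per-species counts) <= 1. Unsupported or
    inconsistent clades are descended through (polytomies likewise, each
    child evaluated independently); a leaf with no supported cross-species
    partner becomes a singleton OG scored as a loss in the absent species.
    """
    present = sorted(set(tree.species_map.values()))
    if len(present) > 2:
        raise ValueError(f"expected at most two species, got {present}")
    if species is None:
        # a single-species tree cannot name its absent sibling; callers that
        # know both labels (e.g. forest processing) should pass them
        species = tuple(present) if len(present) == 2 else (present[0], "__absent__")
    elif set(present) - set(species):
        raise ValueError(f"species map names {present}, outside {species}")
    dtree = tree.to_dendropy()
    if midpoint_root:
        dtree.reroot_at_midpoint(update_bipartitions=False)
    sp_a, sp_b = species

    def species_of(leaf: dendropy.Node) -> str:
        gene = leaf.taxon.label
        try:
            return tree.species_map[gene]
        except KeyError:
            raise ValueError(f"leaf {gene!r} missing from species map") from None

    def collect(node: dendropy.Node) -> tuple[list[str], list[str]]:
        genes_a: list[str] = []
        genes_b: list[str] = []
        for leaf in node.leaf_iter():
            (genes_a if species_of(leaf) == sp_a else genes_b).append(leaf.taxon.label)
        return genes_a, genes_b

    def assign(node: dendropy.Node) -> list[OrthologGroup]:
        if node.is_leaf():
            genes_a, genes_b = collect(node)
            return [_og_from_counts(genes_a, genes_b, sp_a, sp_b)]
        genes_a, genes_b = collect(node)
        consistent = min(len(genes_a), len(genes_b)) <= 1 and (genes_a or genes_b)
        if consistent and _node_support(node) > support_threshold:
            return [_og_from_counts(genes_a, genes_b, sp_a, sp_b)]
        out: list[OrthologGroup] = []
        for child in node.child_nodes():
            out.extend(assign(child))
        return out

    return assign(dtree.seed_node)


def delineate_forest(
    trees: list[GeneTree],
    support_threshold: float = 90.0,
    midpoint_root: bool = False,
    species: tuple[str, str] | None = None,
) -> list[OrthologGroup]:
    if species is None:
        seen = sorted({sp for t in trees for sp in t.species_map.values()})
        if len(seen) != 2:
            raise ValueError(f"forest names {seen}; pass the species pair explicitly")
        species = (seen[0], seen[1])
    ogs: list[OrthologGroup] = []
    for tree in trees:
        ogs.extend(delineate_orthogroups(tree, support_threshold, midpoint_root, species))
    return ogs


def summarize_repertoire(og_sets: dict[str, list[OrthologGroup]]) -> RepertoireSummary:
    """Per-family OG counts, species totals and branch gain/loss totals."""
    summary = RepertoireSummary()
    for family, ogs in og_sets.items():
        if not ogs:
            raise ValueError(f"family {family!r} has no orthologous groups")
        gains = Counter()
        losses = Counter()
        counts = Counter()
        sp_a = ogs[0].species_a
        sp_b = ogs[0].species_b
        for og in ogs:
            og.validate()
            counts[sp_a] += len(og.members_a)
            counts[sp_b] += len(og.members_b)
            gains[sp_a] += og.gains_a
            gains[sp_b] += og.gains_b
            losses[sp_a] += og.losses_a
            losses[sp_b] += og.losses_b
        n_ogs = len(ogs)
        for sp in (sp_a, sp_b):
            if counts[sp] != n_ogs + gains[sp] - losses[sp]:
                raise ValueError(
                    f"bookkeeping violated for family {family!r}, species {sp}"
                )
        summary.families[family] = {
            "n_ogs": n_ogs,
            "mrca_genes": n_ogs,
            "counts": dict(counts),
            "gains": dict(gains),
            "losses": dict(losses),
        }
    return summary
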