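"""Pseudo-reference construction from fixed interspecific differences.

To remove read-mapping bias when quantifying a second species against the
reference genome of its sibling, nucleotides at sites of fixed differences
are replaced with each site's most frequent alternative allele, after
filtering variants on read depth and variant quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO

log = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "SubstitutionReport",
    "load_reference",
    "load_variants",
    "apply_fixed_differences",
    "write_reference",
]


@dataclass(frozen=True)
class VariantRecord:
    """One candidate fixed difference (VCF conventions: 1-based ``pos``)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    depth: int
    quality: float
    allele_counts: tuple[int, ...] = ()  # per alt allele, aligned with alt_alleles

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and all(len(a) == 1 for a in self.alt_alleles)

    def most_frequent_alt(self) -> str:
        """Most frequent alternative allele; ties broken lexicographically."""
        if not self.alt_alleles:
            raise ValueError("variant has no alternative allele")
        if len(self.allele_counts) == len(self.alt_alleles) and self.allele_counts:
            best = max(self.allele_counts)
            return min(a for a, n in zip(self.alt_alleles, self.allele_counts) if n == best)
        return min(self.alt_alleles)


@dataclass
class SubstitutionReport:
    n_candidates: int = 0
    n_snv: int = 0
    n_skipped_indel: int = 0
    n_pass_depth: int = 0
    n_pass_quality: int = 0
    n_substituted: int = 0
    sites: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_candidates": self.n_candidates,
            "n_snv": self.n_snv,
            "n_skipped_indel": self.n_skipped_indel,
            "n_pass_depth": self.n_pass_depth,
            "n_pass_quality": self.n_pass_quality,
            "n_substituted": self.n_substituted,
            "sites": self.sites,
        }


def load_reference(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_reference(reference: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def load_variants(path, depth_field: str = "DP") -> list[VariantRecord]:
    """Read variant records from a VCF via pysam.

    Depth is taken from the INFO field named ``depth_field`` (falling back
    to the sum of the first sample's AD); per-alt observation counts come
    from the first sample's AD when present.
    """
    import pysam

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = tuple(a for a in (rec.alts or ()) if a is not None)
            ad: tuple[int, ...] = ()
            if rec.samples:
                sample = rec.samples[0]
                if "AD" in sample and sample["AD"] is not None:
                    raw = tuple(int(x) for x in sample["AD"] if x is not None)
                    ad = raw[1:]  # first AD entry is the reference allele
            depth = rec.info.get(depth_field)
            if depth is None and ad:
                depth = sum(ad)
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=str(rec.ref),
                    alt_alleles=alts,
                    depth=int(depth or 0),
                    quality=float(rec.qual if rec.qual is not None else 0.0),
                    allele_counts=ad,
                )
            )
    return records


def apply_fixed_differences(
    reference: dict[str, str],
    variants: list[VariantRecord],
    min_depth: int = 5,
    min_quality: float = 60.0,
) -> tuple[dict[str, str], SubstitutionReport]:
    """Substitute passing fixed differences into the reference.

    Only single-nucleotide variants with depth >= ``min_depth`` and
    quality >= ``min_quality`` are substituted, each with its most
    frequent alternative allele. Sequence lengths are preserved. A
    reference-allele mismatch is a hard error (this also guards against
    accidentally applying the same variants twice).
    """
    report = SubstitutionReport()
    seqs = {name: list(seq) for name, seq in reference.items()}
    for var in variants:
        report.n_candidates += 1
        if var.chrom not in seqs:
            raise ValueError(f"variant on unknown sequence {var.chrom!r}")
        if not 1 <= var.pos <= len(seqs[var.chrom]):
            raise ValueError(f"position {var.pos} outside {var.chrom!r}")
        if not var.is_snv:
            report.n_skipped_indel += 1
            log.warning("skipping non-SNV record at %s:%d", var.chrom, var.pos)
            continue
        report.n_snv += 1
        observed = seqs[var.chrom][var.pos - 1]
        if observed != var.ref_allele:
            raise ValueError(
                f"reference mismatch at {var.chrom}:{var.pos}: "
                f"sequence has {observed}, variant claims {var.ref_allele}"
            )
        if var.depth < min_depth:
            continue
        report.n_pass_depth += 1
        if var.quality < min_quality:
            continue
        report.n_pass_quality += 1
        alt = var.most_frequent_alt()
        seqs[var.chrom][var.pos - 1] = alt
        report.n_substituted += 1
        report.sites.append(
            {"chrom": var.chrom, "pos": var.pos, "ref": var.ref_allele, "alt": alt}
        )
    modified = {name: "".join(chars) for name, chars in seqs.items()}
    for name in reference:
        assert len(modified[name]) == len(reference[name])
    return modified, report
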