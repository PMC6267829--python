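"""Maternal-donor inference from shared chloroplast SNP sets.

Chloroplasts are maternally inherited in most angiosperms, so a hybrid's
plastid genome is a near-clone of its maternal parent's.  Given per-species
SNP sets called against a common plastid reference, the maternal lineage is
the side (paternal candidate vs. maternal-candidate clade) sharing the most
SNPs exclusively with the hybrid, and within the winning clade the closest
species is the candidate with the larger hybrid-exclusive pairwise count.

SNP identity is the exact (chrom, pos, ref, alt) tuple — positions shared by
chance with different alleles are not shared ancestry.  Positions are
1-based (VCF convention); multiallelic records are decomposed; indels are
skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from polyorigin.venn import OverlapPartition, venn_from_sets

__all__ = ["SnpRecord", "SnpSet", "SnpSharingTable", "load_snp_set", "snp_venn",
           "infer_maternal"]

SnpRecord = tuple[str, int, str, str]  # (chrom, 1-based pos, ref, alt)


@dataclass(frozen=True)
class SnpSet:
    """Deduplicated biallelic SNPs of one species vs. a plastid reference."""

    species_label: str
    records: frozenset[SnpRecord]

    def __post_init__(self) -> None:
        for chrom, pos, ref, alt in self.records:
            if pos < 1:
                raise ValueError(f"positions are 1-based, got {pos} on {chrom}")
            if ref == alt:
                raise ValueError(f"ref == alt ({ref!r}) at {chrom}:{pos}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class MaternityCall:
    """Outcome of maternal-donor inference.

    ``lineage`` is "maternal", "paternal", "ambiguous" or "uninformative";
    ``species`` names the closest maternal candidate when the maternal clade
    wins unambiguously, else None.
    """

    lineage: str
    species: str | None
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SnpSharingTable:
    partition: OverlapPartition
    call: MaternityCall | None = None

    def to_dict(self) -> dict:
        out = {"region_counts": {r["region"]: r["count"] for r in self.partition.to_rows()}}
        if self.call is not None:
            out["call"] = {
                "lineage": self.call.lineage,
                "species": self.call.species,
                "evidence": self.call.evidence,
            }
        return out


def _parse_tsv(path: Path, label: str) -> set[SnpRecord]:
    records: set[SnpRecord] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom, pos_s, ref, alt = fields[:4]
            if lineno == 1 and not pos_s.isdigit():
                continue  # header row
            try:
                pos = int(pos_s)
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: bad position {pos_s!r}") from e
            for a in alt.split(","):
                if len(ref) != 1 or len(a) != 1:
                    warnings.warn(f"{path}:{lineno}: skipping indel {ref}>{a}")
                    continue
                records.add((chrom, pos, ref.upper(), a.upper()))
    return records


def _parse_vcf(path: Path) -> set[SnpRecord]:
    import pysam

    records: set[SnpRecord] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or alt == "*":
                    warnings.warn(
                        f"{path}: skipping indel {rec.ref}>{alt} at {rec.chrom}:{rec.pos}"
                    )
                    continue
                records.add((rec.chrom, rec.pos, rec.ref.upper(), alt.upper()))
    return records


def load_snp_set(path: str | Path, format: str = "auto", label: str | None = None) -> SnpSet:
    """Load a SNP set from VCF (via pysam) or 4-column TSV (chrom pos ref alt).

    Multiallelic records are decomposed into biallelic entries, duplicates
    collapse, and indels are skipped with a warning.
    """
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix.lower() in {".vcf", ".bcf"} else "tsv"
    if label is None:
        label = path.stem
    if format == "vcf":
        records = _parse_vcf(path)
    elif format == "tsv":
        records = _parse_tsv(path, label)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'vcf' or 'tsv')")
    return SnpSet(label, frozenset(records))


def snp_venn(sets: Sequence[SnpSet]) -> SnpSharingTable:
    """Exclusive-region counts of SNP sets across species (no call)."""
    if len(sets) < 2:
        raise ValueError("need at least 2 SNP sets")
    partition = venn_from_sets({s.species_label: s.records for s in sets})
    return SnpSharingTable(partition)


def infer_maternal(
    hybrid: SnpSet, paternal: SnpSet, maternal_candidates: Sequence[SnpSet]
) -> SnpSharingTable:
    """Call the hybrid's maternal donor from SNP sharing.

    The winning lineage is the side with more SNPs shared with the hybrid
    and private to that side: for the paternal side, SNPs in hybrid and
    paternal but in no maternal candidate; for the maternal side, SNPs in
    the hybrid and at least one maternal candidate but not the paternal
    species.  Within a winning maternal clade the closest species is the
    candidate with the larger exclusive pairwise count (region exactly
    {hybrid, candidate}); ties are reported as "ambiguous".
    """
    if not maternal_candidates:
        raise ValueError("need at least one maternal candidate")
    sets = [hybrid, paternal, *maternal_candidates]
    partition = venn_from_sets({s.species_label: s.records for s in sets})
    h, p = hybrid.species_label, paternal.species_label
    cands = [c.species_label for c in maternal_candidates]

    paternal_side = sum(
        c
        for region, c in partition.region_counts.items()
        if h in region and p in region and not region & set(cands)
    )
    maternal_side = sum(
        c
        for region, c in partition.region_counts.items()
        if h in region and p not in region and region & set(cands)
    )
    evidence: dict = {
        "paternal_side": int(paternal_side),
        "maternal_side": int(maternal_side),
    }
    if paternal_side == 0 and maternal_side == 0:
        call = MaternityCall("uninformative", None, evidence)
    elif paternal_side == maternal_side:
        call = MaternityCall("ambiguous", None, evidence)
    elif paternal_side > maternal_side:
        call = MaternityCall("paternal", paternal.species_label, evidence)
    else:
        pairwise = {c: partition.count(h, c) for c in cands}
        evidence["pairwise_exclusive"] = pairwise
        best = max(pairwise.values())
        winners = sorted(c for c, v in pairwise.items() if v == best)
        if len(cands) == 1:
            call = MaternityCall("maternal", cands[0], evidence)
        elif len(winners) > 1:
            # the maternal clade wins but the closest tip is tied
            call = MaternityCall("maternal", None, evidence)
        else:
            call = MaternityCall("maternal", winners[0], evidence)
    return SnpSharingTable(partition, call)
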