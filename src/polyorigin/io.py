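"""Format readers/writers and run configuration.

Conventions: 1-based coordinates in VCF, 0-based half-open intervals
internally; conversion is confined to this module.  Sequence case is
preserved on round-trip; CRLF and LF inputs parse identically.  Machine
output goes to files/stdout, logging to stderr.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from polyorigin.plastid import SnpRecord
from polyorigin.simdata import Read


def log(stage: str, message: str) -> None:
    print(f"[{stage}] {message}", file=sys.stderr)


# ---------------------------------------------------------------- sequences

def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: sequence}; ids and sequences round-trip losslessly."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq)
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: str | Path) -> list[Read]:
    try:
        return [
            Read(rec.id, str(rec.seq), "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            ))
            for rec in SeqIO.parse(str(path), "fastq")
        ]
    except ValueError as e:
        raise ValueError(f"{path}: malformed FASTQ ({e})") from e


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


# --------------------------------------------------------------------- VCF

def write_vcf(
    records: Iterable[SnpRecord],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Minimal VCF v4.2 (CHROM POS ID REF ALT QUAL FILTER INFO), pysam-readable."""
    records = sorted(set(records))
    if contig_lengths is None:
        contig_lengths = {}
        for chrom, pos, _, _ in records:
            contig_lengths[chrom] = max(contig_lengths.get(chrom, 0), pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(contig_lengths):
            fh.write(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


# --------------------------------------------------------------------- TSV

def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index)


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick.rstrip("\n") + "\n")


# ------------------------------------------------------------------ config

@dataclass
class RunConfig:
    """Validated knobs for an end-to-end run; echoed into report headers."""

    seed: int = 42
    k: int = 31
    d_min: int = 5
    d_max: int = 250
    size_cutoff: int | str = "auto"
    tau: float = 0.05
    r_min: float = 0.9
    transform: str = "none"
    out_dir: str = "polyorigin_out"
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or not 3 <= self.k <= 63:
            raise ValueError(f"k must be odd and in [3, 63], got {self.k}")
        if not 1 <= self.d_min <= self.d_max:
            raise ValueError(f"bad depth band [{self.d_min}, {self.d_max}]")
        if not 0 <= self.tau < 1:
            raise ValueError(f"tau must be in [0, 1), got {self.tau}")
        if self.transform not in ("none", "log10"):
            raise ValueError(f"transform must be 'none' or 'log10', got {self.transform}")
        if self.size_cutoff != "auto":
            self.size_cutoff = int(self.size_cutoff)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**data)


def write_report(report: Mapping, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(
        json.dumps(report, sort_keys=True, indent=2, separators=(",", ": "))
        + "\n"
    )
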