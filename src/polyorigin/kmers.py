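"""K-mer counting, spectrum genome sizing and hybrid subgenome attribution.

The parental-origin signal exploited here is simple: a k-mer (default
k = 31) long enough to be effectively unique in a plant genome acts as a
barcode for the subgenome it came from.  K-mers of a recent allotetraploid
that occur in exactly one putative progenitor's reads are *diagnostic*, and
the ratio of paternal- to maternal-diagnostic k-mers estimates the fraction
of the hybrid genome contributed by each parent.  The same k-mer multiset,
viewed as a depth histogram (the k-mer spectrum), yields a genome-size
estimate: total error-free k-mer instances divided by the modal depth.

K-mers are canonicalized (lexicographic minimum of a window and its reverse
complement) so both strands count as one object; odd k guarantees a k-mer is
never its own reverse complement.  For k <= 31 k-mers are 2-bit packed into
``uint64`` and all counting/set arithmetic is vectorized; for 31 < k <= 63 a
string fallback is used (same semantics, small inputs only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from polyorigin.venn import OverlapPartition, venn_from_arrays

__all__ = [
    "KmerSpectrum",
    "KmerCounts",
    "FilteredKmerSet",
    "GenomeSizeEstimate",
    "ContributionReport",
    "count_kmers",
    "estimate_genome_size",
    "venn_partition",
    "attribute_subgenome",
    "expected_contribution_from_sizes",
    "downsizing_report",
    "whole_genome_reduction_percent",
    "kmer_to_string",
]

# default depth band for cross-species k-mer set comparisons: a k-mer must be
# seen between 5 and 250 times (inclusive) to enter a FilteredKmerSet
DEFAULT_D_MIN = 5
DEFAULT_D_MAX = 250
DEFAULT_K = 31

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError(f"k must be odd (k={k}): odd k has no palindromic k-mers")
    if not 3 <= k <= 63:
        raise ValueError(f"k must be in [3, 63], got {k}")


def _packed_kmers(seq: str, k: int, canonical: bool) -> np.ndarray:
    """All valid k-mer codes of one sequence as uint64 (k <= 31)."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    invalid = codes == 255
    codes = np.where(invalid, 0, codes).astype(np.uint64)
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd |= codes[j : j + m] << np.uint64(2 * (k - 1 - j))
    if canonical:
        rc_codes = np.uint64(3) - codes
        rev = np.zeros(m, dtype=np.uint64)
        for j in range(k):
            rev |= rc_codes[j : j + m] << np.uint64(2 * j)
        out = np.minimum(fwd, rev)
    else:
        out = fwd
    if invalid.any():
        bad = np.cumsum(np.concatenate(([0], invalid.view(np.int8).astype(np.int64))))
        out = out[(bad[k:] - bad[:-k]) == 0]
    return out


def _string_kmers(seq: str, k: int, canonical: bool) -> list[str]:
    seq = seq.upper()
    out = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(c not in "ACGT" for c in w):
            continue
        if canonical:
            rc = _revcomp(w)
            w = w if w <= rc else rc
        out.append(w)
    return out


def kmer_to_string(code: int, k: int) -> str:
    """Decode a 2-bit packed k-mer back to its DNA string."""
    return "".join("ACGT"[(int(code) >> (2 * (k - 1 - j))) & 3] for j in range(k))


@dataclass(frozen=True)
class KmerSpectrum:
    """Histogram of k-mer multiplicity: depth -> number of distinct k-mers."""

    k: int
    histogram: Mapping[int, int]

    def __post_init__(self) -> None:
        for depth, count in self.histogram.items():
            if depth < 1:
                raise ValueError(f"depth must be >= 1, got {depth}")
            if count < 0:
                raise ValueError(f"count must be >= 0, got {count}")

    @property
    def total_instances(self) -> int:
        """Sum over depth x count — total k-mer windows observed."""
        return sum(d * c for d, c in self.histogram.items())

    @property
    def total_distinct(self) -> int:
        return sum(self.histogram.values())

    def to_rows(self) -> list[dict]:
        return [
            {"depth": d, "distinct_kmer_count": int(self.histogram[d])}
            for d in sorted(self.histogram)
        ]


@dataclass(frozen=True)
class FilteredKmerSet:
    """Distinct canonical k-mers of one species with depth in [d_min, d_max].

    ``members`` is a sorted unique numpy array: ``uint64`` packed codes for
    k <= 31, fixed-width strings otherwise.
    """

    species_label: str
    k: int
    members: np.ndarray
    d_min: int = DEFAULT_D_MIN
    d_max: int = DEFAULT_D_MAX

    def __len__(self) -> int:
        return int(self.members.size)

    def __contains__(self, kmer) -> bool:
        i = np.searchsorted(self.members, kmer)
        return bool(i < self.members.size and self.members[i] == kmer)


@dataclass
class KmerCounts:
    """Result of a counting run: distinct k-mers with their depths.

    Acts as both the spectrum source and the store from which depth-filtered
    sets are drawn for cross-species comparison.
    """

    k: int
    kmers: np.ndarray  # sorted unique
    depths: np.ndarray  # aligned with kmers
    canonical: bool = True
    label: str | None = None

    def spectrum(self) -> KmerSpectrum:
        depths, counts = np.unique(self.depths, return_counts=True)
        return KmerSpectrum(self.k, {int(d): int(c) for d, c in zip(depths, counts)})

    def filtered_set(
        self, d_min: int = DEFAULT_D_MIN, d_max: int = DEFAULT_D_MAX
    ) -> FilteredKmerSet:
        if d_min < 1 or d_max < d_min:
            raise ValueError(f"bad depth band [{d_min}, {d_max}]")
        keep = (self.depths >= d_min) & (self.depths <= d_max)
        return FilteredKmerSet(
            self.label or "", self.k, self.kmers[keep], d_min, d_max
        )


def count_kmers(
    sequences: str | Iterable[str],
    k: int = DEFAULT_K,
    canonical: bool = True,
    label: str | None = None,
) -> KmerCounts:
    """Count canonical k-mers over one or many sequences/reads.

    Parameters
    ----------
    sequences
        A single sequence or an iterable of sequences (e.g. reads).  Windows
        containing non-ACGT symbols are skipped.
    k
        Odd k-mer length in [3, 63]; default 31.
    canonical
        Count each k-mer and its reverse complement as one object (the
        lexicographically smaller form).  This is the strand-neutral default
        for unassembled reads.

    Returns
    -------
    KmerCounts
        Distinct k-mers with multiplicities; derive a :class:`KmerSpectrum`
        or a depth-filtered :class:`FilteredKmerSet` from it.
    """
    _validate_k(k)
    if isinstance(sequences, str):
        sequences = [sequences]
    elif isinstance(sequences, Mapping):
        sequences = list(sequences.values())
    else:
        sequences = list(sequences)
    if not sequences:
        raise ValueError("no input sequences")
    if k <= 31:
        # join with a separator so windows never span sequence boundaries
        big = "\0".join(sequences)
        codes = _packed_kmers(big, k, canonical)
        if codes.size == 0:
            warnings.warn("no valid k-mer windows in input (all non-ACGT or too short)")
            return KmerCounts(k, np.empty(0, np.uint64), np.empty(0, np.int64), canonical, label)
        kmers, depths = np.unique(codes, return_counts=True)
    else:
        all_kmers: list[str] = []
        for s in sequences:
            all_kmers.extend(_string_kmers(s, k, canonical))
        if not all_kmers:
            warnings.warn("no valid k-mer windows in input (all non-ACGT or too short)")
            return KmerCounts(k, np.empty(0, f"<U{k}"), np.empty(0, np.int64), canonical, label)
        kmers, depths = np.unique(np.asarray(all_kmers), return_counts=True)
    return KmerCounts(k, kmers, depths.astype(np.int64), canonical, label)


@dataclass(frozen=True)
class GenomeSizeEstimate:
    size_bases: float
    modal_depth: int
    cutoff: int

    @property
    def size_gb(self) -> float:
        return self.size_bases / 1e9


def _auto_cutoff(dense: np.ndarray) -> int:
    """First local minimum of the depth histogram, else the default depth 5.

    Separates the low-depth error peak from the coverage peak.  A depth d is
    the first local minimum when counts stop decreasing: count[d] < count[d-1]
    and count[d] <= count[d+1].
    """
    for d in range(2, dense.size - 1):
        if dense[d] < dense[d - 1] and dense[d] <= dense[d + 1]:
            return d
    return 5


def estimate_genome_size(
    spectrum: KmerSpectrum, error_cutoff: int | str = "auto"
) -> GenomeSizeEstimate:
    """Genome size from a k-mer spectrum.

    Size = (total error-free k-mer instances) / (their most frequent depth):

        G = sum_{d >= cutoff} d * n_d  /  argmax_{d >= cutoff} n_d

    where ``n_d`` is the number of distinct k-mers at depth ``d``.  K-mers
    below the error cutoff are presumed sequencing errors and excluded.
    ``error_cutoff="auto"`` uses the spectrum's first local minimum (the
    valley between the error peak and the coverage peak), falling back to
    depth 5 when the histogram is monotone.  Ties for the modal depth break
    toward the lower depth, deterministically.
    """
    if not spectrum.histogram:
        raise ValueError("empty k-mer spectrum")
    max_d = max(spectrum.histogram)
    dense = np.zeros(max_d + 2, dtype=np.int64)
    for d, c in spectrum.histogram.items():
        dense[d] = c
    if error_cutoff == "auto":
        cutoff = _auto_cutoff(dense)
    else:
        cutoff = int(error_cutoff)
        if cutoff < 1:
            raise ValueError(f"error_cutoff must be >= 1, got {cutoff}")
    above = dense[: max_d + 1].copy()
    above[: min(cutoff, above.size)] = 0
    if above.sum() == 0:
        raise ValueError("spectrum has no homozygous peak above the error cutoff")
    modal_depth = int(np.argmax(above))  # argmax returns first (lowest) on ties
    total = int(np.sum(np.arange(above.size, dtype=np.int64) * above))
    return GenomeSizeEstimate(total / modal_depth, modal_depth, cutoff)


def venn_partition(sets: Sequence[FilteredKmerSet]) -> OverlapPartition:
    """Exact exclusive-region counts over 2–6 filtered k-mer sets."""
    ks = {s.k for s in sets}
    if len(ks) > 1:
        raise ValueError(f"all sets must share k, got {sorted(ks)}")
    return venn_from_arrays({s.species_label: s.members for s in sets})


@dataclass
class ContributionReport:
    """Per-parent genome fractions, Gb contributions and downsizing.

    Fractions are percentages over *diagnostic* k-mers only (those found in
    exactly one parental lineage); they always sum to 100.  Gb fields are
    populated when a hybrid genome size is supplied.  Negative downsizing
    means the subgenome *gained* DNA relative to its parent ("upsizing").
    """

    paternal_label: str
    maternal_label: str
    paternal_fraction: float  # percent
    maternal_fraction: float  # percent
    n_paternal_diagnostic: int | None = None
    n_maternal_diagnostic: int | None = None
    n_shared_both: int | None = None
    n_private_hybrid: int | None = None
    hybrid_size_gb: float | None = None
    paternal_contribution_gb: float | None = None
    maternal_contribution_gb: float | None = None
    paternal_downsizing_gb: float | None = None
    maternal_downsizing_gb: float | None = None
    whole_genome_reduction_percent: float | None = None
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"paternal ({self.paternal_label}): {self.paternal_fraction:.1f}%",
            f"maternal ({self.maternal_label}): {self.maternal_fraction:.1f}%",
        ]
        for side, contrib, down in (
            ("paternal", self.paternal_contribution_gb, self.paternal_downsizing_gb),
            ("maternal", self.maternal_contribution_gb, self.maternal_downsizing_gb),
        ):
            if contrib is not None:
                word = "downsizing" if (down or 0) >= 0 else "upsizing"
                lines.append(
                    f"{side} contribution: {contrib:.2f} Gb"
                    + (f" ({abs(down):.2f} Gb {word})" if down is not None else "")
                )
        if self.whole_genome_reduction_percent is not None:
            lines.append(
                f"whole-genome reduction: {self.whole_genome_reduction_percent:.1f}%"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            k: v for k, v in self.__dict__.items() if k != "extras" and v is not None
        } | ({"extras": self.extras} if self.extras else {})


def attribute_subgenome(
    hybrid: FilteredKmerSet,
    paternal: FilteredKmerSet,
    maternal_lineage: FilteredKmerSet | Sequence[FilteredKmerSet],
    hybrid_size_gb: float | None = None,
) -> ContributionReport:
    """Attribute a hybrid's k-mers to its paternal vs. maternal lineage.

    The maternal lineage may be a single species or several (e.g. two extant
    descendants of the true maternal donor); their k-mer sets are unioned.
    Hybrid k-mers found in exactly one lineage are diagnostic; the paternal
    fraction is ``100 * |S_p| / (|S_p| + |S_m|)``.  K-mers shared with both
    lineages or with neither are reported but excluded from the denominator.
    """
    if isinstance(maternal_lineage, FilteredKmerSet):
        maternal_sets = [maternal_lineage]
    else:
        maternal_sets = list(maternal_lineage)
    ks = {hybrid.k, paternal.k} | {s.k for s in maternal_sets}
    if len(ks) > 1:
        raise ValueError(f"all sets must share k, got {sorted(ks)}")
    maternal_members = np.unique(np.concatenate([s.members for s in maternal_sets]))
    maternal_label = "+".join(s.species_label for s in maternal_sets)

    in_pat = np.isin(hybrid.members, paternal.members, assume_unique=True)
    in_mat = np.isin(hybrid.members, maternal_members, assume_unique=True)
    n_p = int(np.count_nonzero(in_pat & ~in_mat))
    n_m = int(np.count_nonzero(in_mat & ~in_pat))
    n_both = int(np.count_nonzero(in_pat & in_mat))
    n_neither = int(np.count_nonzero(~in_pat & ~in_mat))
    if n_p + n_m == 0:
        raise ValueError("no diagnostic k-mers: hybrid shares nothing exclusively "
                         "with either parental lineage")
    f_p = 100.0 * n_p / (n_p + n_m)
    report = ContributionReport(
        paternal_label=paternal.species_label,
        maternal_label=maternal_label,
        paternal_fraction=f_p,
        maternal_fraction=100.0 - f_p,
        n_paternal_diagnostic=n_p,
        n_maternal_diagnostic=n_m,
        n_shared_both=n_both,
        n_private_hybrid=n_neither,
    )
    if hybrid_size_gb is not None:
        report.hybrid_size_gb = hybrid_size_gb
        report.paternal_contribution_gb = f_p / 100.0 * hybrid_size_gb
        report.maternal_contribution_gb = hybrid_size_gb - report.paternal_contribution_gb
    return report


def expected_contribution_from_sizes(g_a: float, g_b: float) -> tuple[float, float]:
    """Expected percent contributions of two parents from their genome sizes.

    ``(100*G_a/(G_a+G_b), 100*G_b/(G_a+G_b))``, each rounded to one decimal.
    This is the null expectation against which the k-mer-based attribution
    is compared: proportional contribution with no biased loss.
    """
    if g_a <= 0 or g_b <= 0:
        raise ValueError(f"genome sizes must be positive, got ({g_a}, {g_b})")
    f_a = 100.0 * g_a / (g_a + g_b)
    return round(f_a, 1), round(100.0 - f_a, 1)


def whole_genome_reduction_percent(g_hybrid: float, g_a: float, g_b: float) -> float:
    """Percent reduction of a hybrid genome vs. the sum of its parents.

    ``100 * (G_a + G_b - G_h) / (G_a + G_b)``, rounded to one decimal;
    negative when the hybrid is larger than the parental sum.
    """
    if g_hybrid <= 0 or g_a <= 0 or g_b <= 0:
        raise ValueError("genome sizes must be positive")
    total = g_a + g_b
    return round(100.0 * (total - g_hybrid) / total, 1)


def downsizing_report(
    f_p: float,
    g_hybrid: float,
    g_a: float,
    g_b_effective: float,
    paternal_label: str = "paternal",
    maternal_label: str = "maternal",
) -> ContributionReport:
    """Gb contributions and per-parent downsizing from an attribution fraction.

    Parameters
    ----------
    f_p
        Percent of the hybrid genome attributed to parent A (paternal), in
        (0, 100) exclusive.
    g_hybrid, g_a, g_b_effective
        Genome sizes in Gb: the hybrid, parent A, and the effective parent-B
        size (e.g. the average of two candidate maternal species).

    Contributions are ``f_p/100 * G_h`` and the remainder; each parent's
    downsizing is its genome size minus its contribution (negative values
    mean upsizing).  Gb values are rounded to 2 decimals as reported.
    """
    if not 0 < f_p < 100:
        raise ValueError(f"f_p must be in (0, 100), got {f_p}")
    if min(g_hybrid, g_a, g_b_effective) <= 0:
        raise ValueError("genome sizes must be positive")
    contrib_a = f_p / 100.0 * g_hybrid
    contrib_b = g_hybrid - contrib_a
    return ContributionReport(
        paternal_label=paternal_label,
        maternal_label=maternal_label,
        paternal_fraction=round(f_p, 1),
        maternal_fraction=round(100.0 - f_p, 1),
        hybrid_size_gb=g_hybrid,
        paternal_contribution_gb=round(contrib_a, 2),
        maternal_contribution_gb=round(contrib_b, 2),
        paternal_downsizing_gb=round(g_a - contrib_a, 2),
        maternal_downsizing_gb=round(g_b_effective - contrib_b, 2),
        whole_genome_reduction_percent=whole_genome_reduction_percent(
            g_hybrid, g_a, g_b_effective
        ),
    )
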