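"""Seeded synthetic-data generators with known ground truth.

Every generator is a pure function of its configuration and seed and emits
ground truth alongside the data (per-base origin maps, the planted maternal
donor, per-group topology labels, planted correlated gene ids), so each
downstream analysis stage can be tested for exact recovery.

The stated world the defaults describe: two diploid progenitors diverged
~2% per lineage from a common ancestor; an allotetraploid formed by merging
their genomes, optionally losing a few percent of one or both subgenomes as
1-kb segmental deletions; uniform-coverage error-prone short reads;
maternally inherited plastid SNP sets whose sharing structure mirrors the
four-species chloroplast Venn (336 paternal-private / 303 maternal-clade
stem / 17 donor-branch, with small homoplasy extras); peptide ortholog
families evolved down planted topologies; and FPKM-like expression profiles
with designated genes tracking a metabolite at a planted Pearson r.

Substitutions use a Jukes–Cantor-like uniform replacement (a different
base/residue, uniformly); genomes carry no indels so k-mer ground truth
stays exact.  Ortholog families are by default *homoplasy-free*: each
alignment site mutates on at most one branch of the gene tree, making
p-distances exactly additive and planted-topology recovery a guarantee
rather than a probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from polyorigin.phylogeny import COMMON_ANCESTOR, CompositionRule, OrthologGroup
from polyorigin.plastid import SnpRecord, SnpSet

__all__ = [
    "SimulationConfig",
    "ProgenitorSet",
    "Hybrid",
    "Read",
    "PlastidSim",
    "OrthologSim",
    "ExpressionSim",
    "simulate_progenitors",
    "evolve_sequence",
    "hybridize",
    "simulate_reads",
    "simulate_plastid_snps",
    "simulate_ortholog_groups",
    "simulate_expression",
    "default_composition_rule",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

# default species labels for the four-taxon study system: a paternal diploid,
# two extant relatives of the maternal donor, and the tetraploid hybrid
PATERNAL = "undulata"
MATERNAL_TIP_1 = "paniculata"
MATERNAL_TIP_2 = "knightiana"
HYBRID = "rustica"
OUTGROUP = "outgroup"

# chloroplast SNP-sharing region counts of the study system's four-species
# Venn, used as the default plastid fixture template; the maternal donor is
# the tip sharing 17 SNPs exclusively with the hybrid
DEFAULT_PLASTID_REGIONS: dict[tuple[str, ...], int] = {
    (PATERNAL,): 336,
    (HYBRID, PATERNAL): 8,
    (HYBRID, MATERNAL_TIP_1, MATERNAL_TIP_2): 303,
    (HYBRID, MATERNAL_TIP_1): 7,
    (HYBRID, MATERNAL_TIP_2): 17,
    (MATERNAL_TIP_1, MATERNAL_TIP_2): 11,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for every generator; defaults are the stated world above."""

    seed: int = 0
    # genomes
    ancestral_length: int = 100_000
    divergence_per_branch: float = 0.02
    parent_labels: tuple[str, ...] = (PATERNAL, MATERNAL_TIP_2)
    downsizing_fraction: float = 0.0
    downsizing_block: int = 1_000
    # reads
    coverage: float = 30.0
    read_length: int = 100
    error_rate: float = 0.0
    # plastid
    plastid_length: int = 156_000
    plastid_snps_per_branch: int = 300
    plastid_regions: Mapping[tuple[str, ...], int] | str | None = None
    maternal_donor: str = MATERNAL_TIP_2
    # ortholog groups
    n_ortholog_groups: int = 500
    topology_mix: tuple[float, float, float] = (0.42, 0.36, 0.22)
    peptide_length: int = 300
    ortholog_divergence: float = 0.03
    gap_fraction: float = 0.3
    gap_heavy_fraction: float = 0.1
    corrupt_fraction: float = 0.0
    # expression
    expression_samples: tuple[str, ...] = tuple(
        f"{tissue}:{cond}"
        for cond in ("field", "greenhouse_young", "greenhouse_flowering")
        for tissue in ("lower_leaf", "upper_leaf", "root", "flower")
    )
    n_background_genes: int = 500
    n_planted_genes: int = 2
    planted_correlation: float = 0.95

    def __post_init__(self) -> None:
        if self.ancestral_length <= 0:
            raise ValueError("ancestral_length must be positive")
        if not 0.0 <= self.divergence_per_branch < 1.0:
            raise ValueError("divergence_per_branch must be in [0, 1)")
        if not 0.0 <= self.downsizing_fraction < 1.0:
            raise ValueError("downsizing_fraction must be in [0, 1)")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if abs(sum(self.topology_mix) - 1.0) > 1e-9:
            raise ValueError("topology_mix must sum to 1")
        # +/-1 is the zero-noise limit (planted genes become exact affine
        # functions of the metabolite profile)
        if not -1.0 <= self.planted_correlation <= 1.0:
            raise ValueError("planted_correlation must be in [-1, 1]")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _decode(codes: np.ndarray, alphabet: np.ndarray = _BASES) -> str:
    return alphabet[codes].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    lookup = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lookup[b] = i
    codes = lookup[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGT symbols")
    return codes


def evolve_sequence(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, np.ndarray]:
    """Apply independent per-site substitutions at ``rate``.

    Each selected site is replaced by a uniformly chosen *different* base.
    Returns the mutated sequence and the mutated positions (0-based).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"substitution rate must be in [0, 1), got {rate}")
    codes = _encode(seq)
    mask = rng.random(codes.size) < rate
    positions = np.flatnonzero(mask)
    offsets = rng.integers(1, 4, size=positions.size).astype(np.uint8)
    codes[positions] = (codes[positions] + offsets) % 4
    return _decode(codes), positions


@dataclass
class ProgenitorSet:
    ancestor: str
    genomes: dict[str, str]
    mutation_positions: dict[str, np.ndarray]


def simulate_progenitors(config: SimulationConfig) -> ProgenitorSet:
    """Derive one genome per parent label from a common random ancestor."""
    rng = np.random.default_rng(config.seed)
    anc_codes = rng.integers(0, 4, size=config.ancestral_length).astype(np.uint8)
    ancestor = _decode(anc_codes)
    genomes, muts = {}, {}
    for label in config.parent_labels:
        genomes[label], muts[label] = evolve_sequence(
            ancestor, config.divergence_per_branch, rng
        )
    return ProgenitorSet(ancestor, genomes, muts)


@dataclass
class Hybrid:
    sequence: str
    origin: np.ndarray  # uint8 per base: 0 = parent A, 1 = parent B
    parent_labels: tuple[str, str]

    def subgenome_length(self, which: int) -> int:
        return int(np.count_nonzero(self.origin == which))


def _block_deletion_mask(
    length: int, target: int, block: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean keep-mask removing exactly ``target`` bases as random blocks.

    Blocks of ``block`` bases (last one partial) are placed uniformly
    without overlap: draw the inter-block free gaps from a uniform
    composition of the remaining ``length - target`` bases.
    """
    if target == 0:
        return np.ones(length, dtype=bool)
    n_blocks = math.ceil(target / block)
    sizes = [block] * (n_blocks - 1) + [target - block * (n_blocks - 1)]
    free = length - target
    cuts = np.sort(rng.integers(0, free + 1, size=n_blocks))
    keep = np.ones(length, dtype=bool)
    offset = 0
    for gap_end, size in zip(cuts, sizes):
        start = int(gap_end) + offset
        keep[start : start + size] = False
        offset += size
    return keep


def hybridize(
    parent_a: str,
    parent_b: str,
    downsizing_fraction: float = 0.0,
    seed: int = 0,
    block_size: int = 1_000,
    parent_labels: tuple[str, str] = (PATERNAL, MATERNAL_TIP_2),
    downsize: tuple[int, ...] = (0, 1),
) -> Hybrid:
    """Merge two parental genomes into a tetraploid, with block downsizing.

    The hybrid is the concatenation of both parental sequences; from each
    subgenome listed in ``downsize``, exactly
    ``round(downsizing_fraction * len)`` bases are removed as randomly
    placed non-overlapping blocks (default 1 kb, mimicking segmental loss).
    Returns the hybrid with a per-base origin map (0 = parent A, 1 = B).
    """
    if not parent_a or not parent_b:
        raise ValueError("both parental genomes must be non-empty")
    if not 0.0 <= downsizing_fraction < 1.0:
        raise ValueError("downsizing_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    parts, origins = [], []
    for idx, parent in enumerate((parent_a, parent_b)):
        keep = np.ones(len(parent), dtype=bool)
        if idx in downsize and downsizing_fraction > 0:
            target = round(downsizing_fraction * len(parent))
            keep = _block_deletion_mask(len(parent), target, block_size, rng)
        if keep.all():
            kept = parent
        else:
            raw = np.frombuffer(parent.encode("ascii"), dtype=np.uint8)
            kept = raw[keep].tobytes().decode("ascii")
        parts.append(kept)
        origins.append(np.full(len(kept), idx, dtype=np.uint8))
    return Hybrid("".join(parts), np.concatenate(origins), parent_labels)


@dataclass
class Read:
    read_id: str
    sequence: str
    quality: str


def simulate_reads(
    genome: str,
    coverage: float,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    name_prefix: str = "read",
) -> list[Read]:
    """Uniform-coverage single-end reads with per-base substitution errors.

    ``ceil(coverage * len(genome) / read_length)`` reads with uniform start
    positions on the forward strand; each base substituted with probability
    ``error_rate`` (to a uniformly chosen different base).  Qualities are a
    constant placeholder 'I' — the pipeline never consumes them.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    if read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(seed)
    n_reads = math.ceil(coverage * len(genome) / read_length)
    codes = _encode(genome)
    starts = rng.integers(0, len(genome) - read_length + 1, size=n_reads)
    matrix = codes[starts[:, None] + np.arange(read_length)[None, :]]
    if error_rate > 0:
        err = rng.random(matrix.shape) < error_rate
        offsets = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
        matrix[err] = (matrix[err] + offsets) % 4
    qual = "I" * read_length
    return [
        Read(f"{name_prefix}_{i}", _decode(matrix[i]), qual)
        for i in range(n_reads)
    ]


@dataclass
class PlastidSim:
    snp_sets: dict[str, SnpSet]
    maternal_truth: str
    region_counts: dict[tuple[str, ...], int]


def simulate_plastid_snps(config: SimulationConfig) -> PlastidSim:
    """Plant plastid SNP sets with a known sharing structure.

    When ``config.plastid_regions`` is given (or left as the default
    four-species template) each exclusive region of the species Venn
    receives exactly the requested number of biallelic SNPs at unique
    positions, so downstream Venn counts are reproduced exactly.  When
    ``plastid_regions`` is None and only ``plastid_snps_per_branch`` is
    set, a clean lineage tree is used instead: paternal branch, maternal
    clade stem (hybrid + both tips), and the donor branch (hybrid + donor),
    each with that many SNPs — the hybrid inherits its plastid from the
    maternal donor, so it never carries paternal-private SNPs.
    """
    if config.plastid_length <= 0:
        raise ValueError("plastid_length must be positive")
    if config.plastid_regions == "tree":
        # clean lineage tree: no homoplasy, hybrid strictly maternal
        n = config.plastid_snps_per_branch
        regions = {
            (PATERNAL,): n,
            (HYBRID, MATERNAL_TIP_1, MATERNAL_TIP_2): n,
            (HYBRID, config.maternal_donor): n,
        }
    elif config.plastid_regions is not None:
        regions = {tuple(k): int(v) for k, v in config.plastid_regions.items()}
    else:
        # default stated world: the study system's printed four-species Venn
        regions = dict(DEFAULT_PLASTID_REGIONS)
    total = sum(regions.values())
    if total > config.plastid_length:
        raise ValueError("more SNPs requested than plastid positions available")
    rng = np.random.default_rng(config.seed)
    positions = rng.choice(config.plastid_length, size=total, replace=False) + 1
    species = sorted({sp for region in regions for sp in region})
    per_species: dict[str, set[SnpRecord]] = {sp: set() for sp in species}
    cursor = 0
    for region in sorted(regions):
        for _ in range(regions[region]):
            pos = int(positions[cursor])
            cursor += 1
            ref_i = int(rng.integers(0, 4))
            alt_i = (ref_i + int(rng.integers(1, 4))) % 4
            rec: SnpRecord = ("chloroplast", pos, "ACGT"[ref_i], "ACGT"[alt_i])
            for sp in region:
                per_species[sp].add(rec)
    snp_sets = {sp: SnpSet(sp, frozenset(recs)) for sp, recs in per_species.items()}
    return PlastidSim(snp_sets, config.maternal_donor, regions)


def default_composition_rule() -> CompositionRule:
    """The study system's composition expectation: diploids 1, tetraploid 2."""
    return CompositionRule(
        expected_copies={
            OUTGROUP: 1,
            PATERNAL: 1,
            MATERNAL_TIP_1: 1,
            MATERNAL_TIP_2: 1,
            HYBRID: 2,
        },
        outgroup_label=OUTGROUP,
        focal_label=HYBRID,
        paternal_label=PATERNAL,
        maternal_labels=(MATERNAL_TIP_1, MATERNAL_TIP_2),
    )


# branch names of the planted gene tree; the focal homeolog's attachment
# varies with the topology label
_TOPOLOGY_LABELS = (MATERNAL_TIP_1, MATERNAL_TIP_2, COMMON_ANCESTOR)


def _planted_tree_branches(label: str) -> dict[str, tuple[str, ...]]:
    """Map branch name -> leaves below it, for one planted topology."""
    h_pat, h_mat = f"{HYBRID}_A", f"{HYBRID}_B"
    branches = {
        "outgroup": (OUTGROUP,),
        "paternal_clade": (PATERNAL, h_pat),
        "paternal_tip": (PATERNAL,),
        "homeolog_pat": (h_pat,),
        "maternal_clade": (MATERNAL_TIP_1, MATERNAL_TIP_2, h_mat),
        "tip1": (MATERNAL_TIP_1,),
        "tip2": (MATERNAL_TIP_2,),
        "homeolog_mat": (h_mat,),
    }
    if label == MATERNAL_TIP_1:
        branches["donor_pair"] = (MATERNAL_TIP_1, h_mat)
    elif label == MATERNAL_TIP_2:
        branches["donor_pair"] = (MATERNAL_TIP_2, h_mat)
    elif label == COMMON_ANCESTOR:
        branches["tips_pair"] = (MATERNAL_TIP_1, MATERNAL_TIP_2)
    else:
        raise ValueError(f"unknown topology label {label!r}")
    return branches


@dataclass
class OrthologSim:
    groups: list[OrthologGroup]
    truth: pd.DataFrame  # group_id, topology, corrupted, gap_class
    rule: CompositionRule


def simulate_ortholog_groups(config: SimulationConfig) -> OrthologSim:
    """Peptide ortholog families evolved down planted topologies.

    Each group holds one gene per diploid, two homeologs for the
    tetraploid and one outgroup gene, all derived from a random ancestral
    peptide by per-branch substitutions.  Substitution sites are sampled
    without replacement across the whole tree (homoplasy-free), so
    p-distances are exactly additive and tree recovery is exact.

    A ``gap_fraction`` of groups receives leading/trailing gap runs in one
    sequence (exercising terminal trimming); of these, ``gap_heavy_fraction``
    of all groups additionally get >5% interior gap columns in one sequence
    (ground-truth drop for the gap filter).  ``corrupt_fraction`` of groups
    get a duplicated diploid gene (ground-truth drop for the composition
    filter).
    """
    mix = np.asarray(config.topology_mix, dtype=float)
    if mix.size != 3 or (mix < 0).any():
        raise ValueError("topology_mix must be 3 non-negative proportions")
    rng = np.random.default_rng(config.seed)
    L = config.peptide_length
    n_aa = _AA.size
    groups: list[OrthologGroup] = []
    rows = []
    labels = rng.choice(3, size=config.n_ortholog_groups, p=mix / mix.sum())
    for gi in range(config.n_ortholog_groups):
        topo = _TOPOLOGY_LABELS[int(labels[gi])]
        branches = _planted_tree_branches(topo)
        n_sub = max(1, round(config.ortholog_divergence * L))
        need = n_sub * len(branches)
        if need > L:
            raise ValueError(
                f"homoplasy-free evolution needs {need} sites but peptide_length={L}"
            )
        sites = rng.choice(L, size=need, replace=False)
        ancestor = rng.integers(0, n_aa, size=L).astype(np.uint8)
        leaf_names = [OUTGROUP, PATERNAL, MATERNAL_TIP_1, MATERNAL_TIP_2,
                      f"{HYBRID}_A", f"{HYBRID}_B"]
        seqs = {leaf: ancestor.copy() for leaf in leaf_names}
        for bi, (branch, below) in enumerate(sorted(branches.items())):
            branch_sites = sites[bi * n_sub : (bi + 1) * n_sub]
            offsets = rng.integers(1, n_aa, size=n_sub).astype(np.uint8)
            for leaf in below:
                seqs[leaf][branch_sites] = (
                    seqs[leaf][branch_sites] + offsets
                ) % n_aa
        aln = {leaf: _decode(codes, _AA) for leaf, codes in seqs.items()}

        gap_class = "none"
        u = rng.random()
        if u < config.gap_heavy_fraction:
            gap_class = "heavy"
        elif u < config.gap_fraction:
            gap_class = "light"
        if gap_class != "none":
            victim = leaf_names[int(rng.integers(0, len(leaf_names)))]
            lead = int(rng.integers(3, 12))
            trail = int(rng.integers(3, 12))
            s = aln[victim]
            s = "-" * lead + s[lead : L - trail] + "-" * trail
            if gap_class == "heavy":
                # >5% interior gap columns in the trimmed core
                core = np.arange(lead + 5, L - trail - 5)
                n_gaps = int(0.08 * (L - lead - trail)) + 1
                gap_pos = rng.choice(core, size=n_gaps, replace=False)
                chars = np.array(list(s))
                chars[gap_pos] = "-"
                s = "".join(chars)
            aln[victim] = s

        gid = f"OG{gi:05d}"
        gene_of = {leaf: f"{gid}|{leaf}" for leaf in leaf_names}
        members = [
            (leaf.split("_")[0] if leaf.startswith(HYBRID) else leaf, gene_of[leaf])
            for leaf in leaf_names
        ]
        alignment = {gene_of[leaf]: aln[leaf] for leaf in leaf_names}

        corrupted = bool(rng.random() < config.corrupt_fraction)
        if corrupted:
            # duplicate a diploid gene: composition no longer matches
            members.append((PATERNAL, f"{gid}|{PATERNAL}_dup"))
            alignment[f"{gid}|{PATERNAL}_dup"] = aln[PATERNAL]

        groups.append(OrthologGroup(gid, members, alignment))
        rows.append(
            {
                "group_id": gid,
                "topology": topo,
                "corrupted": corrupted,
                "gap_class": gap_class,
            }
        )
    truth = pd.DataFrame(rows)
    return OrthologSim(groups, truth, default_composition_rule())


@dataclass
class ExpressionSim:
    expression: pd.DataFrame  # genes x samples, FPKM-like
    metabolite: pd.Series  # per-sample concentration
    planted_ids: list[str]
    planted_correlation: float


def simulate_expression(config: SimulationConfig) -> ExpressionSim:
    """FPKM-like expression with designated genes tracking a metabolite.

    Background genes are i.i.d. log-normal (heavy-tailed positive, like
    FPKM).  Each planted gene is an affine function of the metabolite
    profile plus Gaussian noise with variance chosen so the population
    Pearson r (metabolite profile held fixed) equals
    ``planted_correlation``; a positive intercept keeps values positive.
    """
    samples = list(config.expression_samples)
    if len(samples) < 3:
        raise ValueError("need at least 3 expression samples")
    r = config.planted_correlation
    rng = np.random.default_rng(config.seed)
    # nicotine-like concentrations: positive, spanning ~an order of magnitude
    metab = pd.Series(
        rng.lognormal(mean=np.log(10.0), sigma=0.8, size=len(samples)),
        index=samples,
        name="metabolite",
    )
    n_bg = config.n_background_genes
    bg = rng.lognormal(mean=2.0, sigma=1.2, size=(n_bg, len(samples)))
    gene_ids = [f"gene{j:05d}" for j in range(n_bg)]
    planted_ids = [f"planted{j}" for j in range(config.n_planted_genes)]
    m = metab.to_numpy()
    s_m = m.std(ddof=1)
    planted_rows = []
    for _ in planted_ids:
        a = 2.0
        if abs(r) < 1e-12:
            sigma = 1.0
            a = 0.0
        else:
            sigma = abs(a) * s_m * math.sqrt(1.0 / r**2 - 1.0)
            if r < 0:
                a = -a
        eps = rng.normal(0.0, sigma, size=len(samples))
        base = a * m + eps
        row = base - base.min() + 1.0  # shift positive; affine, preserves r
        planted_rows.append(row)
    expr = pd.DataFrame(
        np.vstack([bg] + [np.asarray(planted_rows).reshape(len(planted_ids), -1)])
        if planted_ids
        else bg,
        index=gene_ids + planted_ids,
        columns=samples,
    )
    return ExpressionSim(expr, metab, planted_ids, r)
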