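"""Tree-based homeolog ancestry assignment for allotetraploid gene families.

Pipeline per ortholog group: check polyploid composition (one gene per
diploid, two per tetraploid, one outgroup) -> trim terminal gapped columns
from the peptide alignment -> drop alignments where any sequence is more
than 5% gaps -> build a neighbor-joining tree on p-distances -> root at the
outgroup -> read off the sister lineage of the focal tetraploid homeolog.

One homeolog is expected sister to the known paternal diploid; the other
(focal) homeolog is assigned to whichever maternal candidate it is sister
to, or to their common ancestor when it is sister to the clade containing
both.  Groups violating the expected arrangement are labelled "conflict"
and excluded from the informative tally.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "OrthologGroup",
    "CompositionRule",
    "PhyloTree",
    "AncestryTally",
    "COMMON_ANCESTOR",
    "CONFLICT",
    "filter_by_composition",
    "trim_alignment",
    "gap_filter",
    "p_distance_matrix",
    "neighbor_joining",
    "assign_ancestry",
    "tally",
]

GAP = "-"
COMMON_ANCESTOR = "common_ancestor"
CONFLICT = "conflict"

# residues that participate in p-distance comparisons; gaps and ambiguity
# codes (X, B, Z, ...) are excluded from comparable columns
_CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class OrthologGroup:
    """One ortholog group: members plus an aligned peptide alignment."""

    group_id: str
    members: list[tuple[str, str]]  # (species_label, gene_id)
    alignment: dict[str, str]  # gene_id -> aligned sequence

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.alignment.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"group {self.group_id}: aligned sequences differ in length {lengths}"
            )

    def species_of(self) -> dict[str, str]:
        return {gene: sp for sp, gene in self.members}

    def species_counts(self) -> Counter:
        return Counter(sp for sp, _ in self.members)


@dataclass(frozen=True)
class CompositionRule:
    """Expected per-species gene copy numbers plus lineage roles.

    ``expected_copies`` is the polyploidy expectation (diploids 1 copy,
    tetraploids 2).  The lineage roles pin down the constraint topology for
    ancestry assignment: the focal tetraploid, its known paternal diploid,
    and the two candidate maternal diploids.
    """

    expected_copies: Mapping[str, int]
    outgroup_label: str
    focal_label: str
    paternal_label: str
    maternal_labels: tuple[str, str]

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.expected_copies.values()):
            raise ValueError("expected copy counts must be >= 1")
        for lab in (self.outgroup_label, self.focal_label, self.paternal_label,
                    *self.maternal_labels):
            if lab not in self.expected_copies:
                raise ValueError(f"role label {lab!r} missing from expected_copies")


def filter_by_composition(
    groups: Iterable[OrthologGroup], rule: CompositionRule
) -> tuple[list[OrthologGroup], dict]:
    """Retain groups whose species composition exactly matches the rule.

    A group passes iff its member counts equal ``expected_copies`` for every
    species — no missing species, no extra copies, no foreign species.
    Returns (retained, attrition) where attrition reports input/retained/
    dropped counts.
    """
    expected = dict(rule.expected_copies)
    retained, dropped = [], 0
    for g in groups:
        if dict(g.species_counts()) == expected:
            retained.append(g)
        else:
            dropped += 1
    attrition = {
        "input": len(retained) + dropped,
        "retained": len(retained),
        "dropped_composition": dropped,
    }
    return retained, attrition


class TrimError(ValueError):
    """Raised when an alignment has no gap-free column to anchor trimming."""


def trim_alignment(alignment: Mapping[str, str]) -> dict[str, str]:
    """Trim terminal gapped regions, keeping the core consensus block.

    Removes leading columns before the first column with zero gaps across
    all sequences, and trailing columns after the last such column.
    Interior columns are untouched.  Raises :class:`TrimError` when no
    gap-free column exists anywhere.
    """
    if not alignment:
        raise ValueError("empty alignment")
    mat = np.array([list(s) for s in alignment.values()])
    gap_free = ~(mat == GAP).any(axis=0)
    idx = np.flatnonzero(gap_free)
    if idx.size == 0:
        raise TrimError("no gap-free column: cannot anchor terminal trimming")
    lo, hi = int(idx[0]), int(idx[-1]) + 1
    return {gene: seq[lo:hi] for gene, seq in alignment.items()}


def gap_filter(alignment: Mapping[str, str], tau: float = 0.05) -> bool:
    """True (keep) unless any sequence's gap fraction strictly exceeds tau."""
    if not alignment:
        raise ValueError("empty alignment")
    for seq in alignment.values():
        if len(seq) and seq.count(GAP) / len(seq) > tau:
            return False
    return True


def p_distance_matrix(
    alignment: Mapping[str, str]
) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distances: mismatches over comparable (ungapped) columns.

    Columns where either sequence carries a gap or a non-canonical residue
    are excluded from that pair's comparison.  Raises when a pair shares no
    comparable column.
    """
    labels = list(alignment)
    if len(labels) < 3:
        raise ValueError(f"need >= 3 sequences, got {len(labels)}")
    mat = np.array([list(alignment[g].upper()) for g in labels])
    valid = np.isin(mat, sorted(_CANONICAL_RESIDUES))
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = valid[i] & valid[j]
            n_comp = int(comparable.sum())
            if n_comp == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            mism = int((mat[i][comparable] != mat[j][comparable]).sum())
            dist[i, j] = dist[j, i] = mism / n_comp
    return labels, dist


class PhyloTree:
    """Thin wrapper over a dendropy tree with deterministic Newick output."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def branch_length_to(self, label_a: str, label_b: str) -> float:
        """Path length between two leaves (for testing additivity)."""
        pdm = self.tree.phylogenetic_distance_matrix()
        tax = {t.label: t for t in self.tree.taxon_namespace}
        return float(pdm.distance(tax[label_a], tax[label_b]))

    def topology_key(self) -> frozenset:
        """Unrooted topology as the set of non-trivial leaf bipartitions."""
        leaves = frozenset(self.leaf_labels)
        splits = set()
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is None or edge.head_node.is_leaf():
                continue
            side = frozenset(
                lf.taxon.label for lf in edge.head_node.leaf_iter()
            )
            if 1 < len(side) < len(leaves) - 1:
                splits.add(frozenset({side, leaves - side}))
        return frozenset(splits)


def _nj_validate(dist: np.ndarray, labels: Sequence[str]) -> None:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if dist.shape[0] != len(labels):
        raise ValueError("labels do not match matrix dimension")
    if dist.shape[0] < 3:
        raise ValueError("need >= 3 taxa")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal must be zero")


def neighbor_joining(
    dist: np.ndarray, labels: Sequence[str]
) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined; exact Q ties break by lexicographic order of the pair's sorted
    leaf-name keys.  Negative branch lengths are clamped to zero.  Returns
    an unrooted tree (trifurcating central node).
    """
    _nj_validate(dist, labels)
    labels = list(labels)
    tns = dendropy.TaxonNamespace(labels)
    nodes: dict[str, dendropy.Node] = {}
    for lab in labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes[lab] = node
    # sort key per active node: smallest leaf label underneath
    active = sorted(labels)
    D = {
        (a, b): float(dist[labels.index(a), labels.index(b)])
        for a in labels
        for b in labels
        if a != b
    }

    def d(a: str, b: str) -> float:
        return 0.0 if a == b else D[(a, b)]

    while len(active) > 3:
        n = len(active)
        r = {a: sum(d(a, b) for b in active) for a in active}
        best, best_q = None, np.inf
        for i in range(n):
            for j in range(i + 1, n):
                a, b = active[i], active[j]
                q = (n - 2) * d(a, b) - r[a] - r[b]
                if q < best_q - 1e-12:
                    best, best_q = (a, b), q
        a, b = best
        la = 0.5 * d(a, b) + (r[a] - r[b]) / (2 * (n - 2))
        lb = d(a, b) - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent = dendropy.Node()
        for child, length in ((nodes[a], la), (nodes[b], lb)):
            parent.add_child(child)
            child.edge.length = length
        key = min(a, b)
        nodes[key] = parent
        new_active = [x for x in active if x not in (a, b)]
        for x in new_active:
            D[(key, x)] = D[(x, key)] = 0.5 * (d(a, x) + d(b, x) - d(a, b))
        active = sorted(new_active + [key])

    # resolve the final 3 nodes with the closed-form star
    a, b, c = active
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    root = dendropy.Node()
    for x, lx in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[x])
        nodes[x].edge.length = max(lx, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree)


def assign_ancestry(
    tree: PhyloTree,
    species_of: Mapping[str, str],
    rule: CompositionRule,
) -> str:
    """Assign the focal tetraploid homeolog to its nearest progenitor lineage.

    Roots the tree at the outgroup, locates the homeolog sister to the
    paternal diploid (the paternal-subgenome copy), and classifies the
    remaining focal homeolog by its sister group: one maternal candidate,
    the other, or the clade containing both (-> ``common_ancestor``).  Any
    other arrangement returns ``conflict``.
    """
    tree = PhyloTree(tree.tree.clone(depth=1))
    leaves = list(tree.tree.leaf_node_iter())
    by_species: dict[str, list] = {}
    for lf in leaves:
        gene = lf.taxon.label
        sp = species_of.get(gene)
        if sp is None:
            raise ValueError(f"gene {gene!r} missing from species map")
        by_species.setdefault(sp, []).append(lf)

    out_leaves = by_species.get(rule.outgroup_label, [])
    if len(out_leaves) != 1:
        raise ValueError(
            f"expected exactly one outgroup leaf, found {len(out_leaves)}"
        )
    focal_leaves = by_species.get(rule.focal_label, [])
    if len(focal_leaves) != 2:
        return CONFLICT
    pat_leaves = by_species.get(rule.paternal_label, [])
    if len(pat_leaves) != 1:
        return CONFLICT

    out_leaf = out_leaves[0]
    tree.tree.reroot_at_edge(
        out_leaf.edge, update_bipartitions=False, suppress_unifurcations=True
    )

    def sister_species(leaf) -> list[set[str]]:
        """Species sets of the sibling subtrees of a leaf."""
        parent = leaf.parent_node
        if parent is None:
            return []
        return [
            {species_of[x.taxon.label] for x in sib.leaf_iter()}
            for sib in parent.child_nodes()
            if sib is not leaf
        ]

    paternal_sp = rule.paternal_label
    # identify the paternal-subgenome homeolog: sister to exactly the
    # paternal diploid gene
    paternal_copy = None
    for lf in focal_leaves:
        sibs = sister_species(lf)
        if len(sibs) == 1 and sibs[0] == {paternal_sp}:
            paternal_copy = lf
            break
    if paternal_copy is None:
        return CONFLICT
    focal = next(lf for lf in focal_leaves if lf is not paternal_copy)

    sibs = sister_species(focal)
    if len(sibs) != 1:
        return CONFLICT
    sib = sibs[0]
    m1, m2 = rule.maternal_labels
    if sib == {m1}:
        return m1
    if sib == {m2}:
        return m2
    if sib == {m1, m2}:
        return COMMON_ANCESTOR
    return CONFLICT


@dataclass
class AncestryTally:
    """Counts of per-group ancestry assignments plus attrition bookkeeping."""

    counts: dict[str, int]
    informative_categories: tuple[str, ...]
    attrition: dict = field(default_factory=dict)

    @property
    def informative_total(self) -> int:
        return sum(self.counts.get(c, 0) for c in self.informative_categories)

    @property
    def conflict_count(self) -> int:
        return self.counts.get(CONFLICT, 0)

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "informative_total": self.informative_total,
            "attrition": dict(self.attrition),
        }


def tally(
    assignments: Iterable[str],
    rule: CompositionRule | None = None,
    attrition: dict | None = None,
) -> AncestryTally:
    """Tally per-group assignments into an :class:`AncestryTally`.

    The informative categories are the two maternal tips and the common
    ancestor; conflicts are counted separately and excluded from the
    informative total.
    """
    counts = dict(Counter(assignments))
    if rule is not None:
        informative = (*rule.maternal_labels, COMMON_ANCESTOR)
    else:
        informative = tuple(sorted(c for c in counts if c != CONFLICT))
    t = AncestryTally(counts, informative, attrition or {})
    n_clean = sum(v for k, v in counts.items() if k != CONFLICT)
    if t.informative_total != n_clean:
        raise ValueError(
            f"informative categories {informative} do not cover all "
            f"non-conflict assignments ({t.informative_total} != {n_clean})"
        )
    return t
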