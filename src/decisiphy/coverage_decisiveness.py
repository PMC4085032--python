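"""Taxon-by-locus coverage and phylogenetic data decisiveness.

An internal edge of a binary unrooted tree splits the tips into four blocks
(two subtrees at each endpoint). A locus can possibly inform that edge only
if it samples at least one taxon from every block — the four-way partition
property. This module builds the presence matrix from an alignment plus a
partition map, counts decisive loci per branch of an observed tree, and
measures partial decisiveness *d*: the proportion of internal edges, over all
binary unrooted labeled trees on the taxon set, with at least one decisive
locus — exactly for small taxon sets, by Monte Carlo otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trees_io import MISSING_CHARS, Alignment, PartitionMap, Tree, Node, ValidationError

__all__ = [
    "CoverageMatrix",
    "FourWayPartition",
    "DecisivenessEstimate",
    "build_coverage",
    "missingness_summary",
    "four_way_partition",
    "locus_is_decisive",
    "branchwise_decisive_counts",
    "enumerate_partial_decisiveness",
    "estimate_partial_decisiveness",
    "n_unrooted_trees",
]

ENUMERATION_MAX_TAXA = 9


@dataclass
class CoverageMatrix:
    """Boolean taxon × locus presence structure.

    presence[t, l] is True iff taxon t has at least one data character inside
    locus l's columns.
    """

    taxa: list[str]
    loci: list[str]
    presence: np.ndarray

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.taxa), len(self.loci)):
            raise ValidationError("coverage matrix shape mismatch")
        self._taxon_index = {t: i for i, t in enumerate(self.taxa)}

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_taxa(self, locus: str) -> frozenset:
        j = self.loci.index(locus)
        return frozenset(
            t for t, present in zip(self.taxa, self.presence[:, j]) if present
        )

    def locus_taxon_sets(self) -> list[frozenset]:
        return [self.locus_taxa(l) for l in self.loci]

    def locus_bitmasks(self, taxon_order: list[str] | None = None) -> list[int]:
        """Per-locus taxon sets as bitmasks over `taxon_order` (default: own
        taxon order). Bit i corresponds to taxon_order[i]."""
        order = taxon_order if taxon_order is not None else self.taxa
        masks = []
        for j in range(self.n_loci):
            m = 0
            for i, t in enumerate(order):
                if self.presence[self._taxon_index[t], j]:
                    m |= 1 << i
            masks.append(m)
        return masks

    def empty_taxa(self) -> list[str]:
        return [t for t, row in zip(self.taxa, self.presence) if not row.any()]


@dataclass(frozen=True)
class FourWayPartition:
    """The four disjoint non-empty tip blocks induced by an internal edge:
    the two daughter subtrees at one endpoint (A1, A2) and the two at the
    other (B1, B2: sister subtree and rest of tree)."""

    edge_key: str
    A1: frozenset
    A2: frozenset
    B1: frozenset
    B2: frozenset

    @property
    def blocks(self) -> tuple[frozenset, frozenset, frozenset, frozenset]:
        return (self.A1, self.A2, self.B1, self.B2)


@dataclass
class DecisivenessEstimate:
    d_hat: float
    se: float
    n_trees: int
    seed: int

    def __post_init__(self):
        if not (0.0 <= self.d_hat <= 1.0):
            raise ValidationError(f"d_hat {self.d_hat} outside [0, 1]")


# ---------------------------------------------------------------------------
# coverage construction and missingness
# ---------------------------------------------------------------------------


def build_coverage(
    alignment: Alignment,
    partitions: PartitionMap,
    missing_chars=MISSING_CHARS,
) -> CoverageMatrix:
    """Presence matrix: a (taxon, locus) cell is present iff the taxon has at
    least one data character within the locus columns. Taxa empty at every
    locus are retained (they may still appear in trees) but reported via
    :meth:`CoverageMatrix.empty_taxa`."""
    partitions.check_within(alignment.n_sites)
    data = alignment.data_mask(missing_chars)
    loci = partitions.loci
    presence = np.zeros((alignment.n_taxa, len(loci)), dtype=bool)
    for j, locus in enumerate(loci):
        presence[:, j] = data[:, partitions.columns(locus)].any(axis=1)
    return CoverageMatrix(list(alignment.taxa), loci, presence)


def missingness_summary(
    alignment: Alignment,
    partitions: PartitionMap,
    missing_chars=MISSING_CHARS,
) -> dict:
    """Cellwise and taxon×locus missingness percentages plus site-pattern
    count (number of distinct alignment columns)."""
    data = alignment.data_mask(missing_chars)
    n_cells = alignment.n_taxa * alignment.n_sites
    cellwise = 100.0 * (1.0 - data.sum() / n_cells) if n_cells else 0.0
    coverage = build_coverage(alignment, partitions, missing_chars)
    tl_cells = coverage.n_taxa * coverage.n_loci
    tl_missing = 100.0 * (1.0 - coverage.presence.sum() / tl_cells) if tl_cells else 0.0
    patterns = np.unique(alignment.data.T, axis=0).shape[0] if alignment.n_sites else 0
    return {
        "cellwise_missing_pct": float(cellwise),
        "taxon_locus_missing_pct": float(tl_missing),
        "n_sites": int(alignment.n_sites),
        "n_site_patterns": int(patterns),
    }


# ---------------------------------------------------------------------------
# four-way partitions on an observed tree
# ---------------------------------------------------------------------------


def four_way_partition(tree: Tree, edge: Node) -> FourWayPartition:
    """Blocks of the four-way partition for an internal edge of the unrooted
    view of `tree` (edge identified by the node below it)."""
    sets = tree._leafsets()
    all_tips = sets[id(tree.root)]
    if edge.is_leaf or edge.parent is None:
        raise ValidationError("no four-way partition for terminal branches")
    if len(edge.children) != 2:
        raise ValidationError("four-way partitions require a binary tree")
    A1 = sets[id(edge.children[0])]
    A2 = sets[id(edge.children[1])]

    parent = edge.parent
    if parent is tree.root and tree.has_bifurcating_root:
        # unrooted view suppresses the root: the other endpoint is the sibling
        sibling = next(c for c in parent.children if c is not edge)
        if sibling.is_leaf or len(sibling.children) != 2:
            raise ValidationError("no four-way partition for terminal branches")
        B1 = sets[id(sibling.children[0])]
        B2 = sets[id(sibling.children[1])]
    elif parent is tree.root and len(parent.children) == 3:
        others = [c for c in parent.children if c is not edge]
        B1 = sets[id(others[0])]
        B2 = sets[id(others[1])]
    else:
        if len(parent.children) != 2:
            raise ValidationError("four-way partitions require a binary tree")
        sibling = next(c for c in parent.children if c is not edge)
        B1 = sets[id(sibling)]
        B2 = all_tips - sets[id(parent)]
    for block in (A1, A2, B1, B2):
        if not block:
            raise ValidationError("no four-way partition for terminal branches")
    return FourWayPartition(tree.edge_key(edge), A1, A2, B1, B2)


def locus_is_decisive(fwp: FourWayPartition, locus_taxa: frozenset) -> bool:
    """True iff the locus samples at least one taxon in every block."""
    return all(locus_taxa & block for block in fwp.blocks)


def branchwise_decisive_counts(tree: Tree, coverage: CoverageMatrix) -> dict[str, int]:
    """Number of decisive loci for each internal edge of the unrooted view,
    keyed by canonical bipartition string."""
    missing = set(tree.tip_labels) - set(coverage.taxa)
    if missing:
        raise ValidationError(f"tips absent from coverage matrix: {sorted(missing)}")
    locus_sets = coverage.locus_taxon_sets()
    counts = {}
    for edge in tree.internal_edges():
        fwp = four_way_partition(tree, edge)
        counts[fwp.edge_key] = sum(
            1 for taxa in locus_sets if locus_is_decisive(fwp, taxa)
        )
    return counts


# ---------------------------------------------------------------------------
# partial decisiveness d over all binary unrooted labeled trees
# ---------------------------------------------------------------------------


def n_unrooted_trees(n: int) -> int:
    """(2n-5)!! — number of unrooted binary labeled trees on n >= 3 tips."""
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


class _EdgeTree:
    """Mutable unrooted tree over integer node ids for enumeration/sampling.

    Tips are 0..n-1; internal nodes get ids >= n. Grown by splitting an edge
    with the next tip (the (2k-3)-edge insertion bijection, which makes both
    exhaustive enumeration and uniform sampling straightforward).
    """

    __slots__ = ("n", "adj", "edges", "next_internal")

    def __init__(self, n: int):
        self.n = n
        # star on first three tips
        c = n
        self.adj = {0: [c], 1: [c], 2: [c], c: [0, 1, 2]}
        self.edges = [(0, c), (1, c), (2, c)]
        self.next_internal = n + 1

    def attach(self, tip: int, edge_index: int) -> tuple:
        u, v = self.edges[edge_index]
        m = self.next_internal
        self.next_internal += 1
        self.adj[u][self.adj[u].index(v)] = m
        self.adj[v][self.adj[v].index(u)] = m
        self.adj[m] = [u, v, tip]
        self.adj[tip] = [m]
        self.edges[edge_index] = (u, m)
        self.edges.append((m, v))
        self.edges.append((m, tip))
        return (edge_index, u, v, m, tip)

    def detach(self, token) -> None:
        edge_index, u, v, m, tip = token
        self.edges.pop()
        self.edges.pop()
        self.edges[edge_index] = (u, v)
        self.adj[u][self.adj[u].index(m)] = v
        self.adj[v][self.adj[v].index(m)] = u
        del self.adj[m]
        del self.adj[tip]
        self.next_internal -= 1

    def decisive_edge_fraction(self, locus_masks: list[int]) -> float:
        """Fraction of internal edges with >= 1 locus intersecting all four
        blocks. Blocks are computed as tip bitmasks via one rooted pass."""
        n = self.n
        full = (1 << n) - 1
        # root at tip 0's neighbor; compute down-masks by iterative postorder
        root = self.adj[0][0]
        parent = {root: 0}
        order = []
        stack = [root]
        while stack:
            node = stack.pop()
            order.append(node)
            for nb in self.adj[node]:
                if nb != parent[node]:
                    parent[nb] = node
                    stack.append(nb)
        down = {}
        for node in reversed(order):
            if node < n:
                down[node] = 1 << node
            else:
                acc = 0
                for nb in self.adj[node]:
                    if nb != parent[node]:
                        acc |= down[nb]
                down[node] = acc
        n_internal = 0
        n_decisive = 0
        for node in order:
            if node < n or node == root:
                continue
            # edge (parent[node], node) is internal: node internal, and the
            # parent side contains >= 2 tips (it always does: tip 0 + sibling)
            u = parent[node]
            kids = [nb for nb in self.adj[node] if nb != u]
            a1, a2 = down[kids[0]], down[kids[1]]
            pu = parent[u]
            sib = next(nb for nb in self.adj[u] if nb != pu and nb != node)
            b1 = down[sib]
            b2 = full & ~down[u]
            n_internal += 1
            for mask in locus_masks:
                if (mask & a1) and (mask & a2) and (mask & b1) and (mask & b2):
                    n_decisive += 1
                    break
        if n_internal == 0:
            return 1.0
        return n_decisive / n_internal


def enumerate_partial_decisiveness(coverage: CoverageMatrix) -> float:
    """Exact d by exhaustive enumeration of all unrooted binary labeled trees
    (feasible up to 9 taxa; use the Monte-Carlo estimator beyond that)."""
    n = coverage.n_taxa
    if n < 4:
        raise ValidationError("partial decisiveness needs at least 4 taxa")
    if n > ENUMERATION_MAX_TAXA:
        raise ValidationError(
            f"{n} taxa exceed the enumeration bound of {ENUMERATION_MAX_TAXA}; "
            "use estimate_partial_decisiveness"
        )
    masks = coverage.locus_bitmasks()
    tree = _EdgeTree(n)
    total = {"sum": 0.0, "count": 0}

    def recurse(next_tip: int):
        if next_tip == n:
            total["sum"] += tree.decisive_edge_fraction(masks)
            total["count"] += 1
            return
        for ei in range(len(tree.edges)):
            token = tree.attach(next_tip, ei)
            recurse(next_tip + 1)
            tree.detach(token)

    recurse(3)
    assert total["count"] == n_unrooted_trees(n)
    return total["sum"] / total["count"]


def estimate_partial_decisiveness(
    coverage: CoverageMatrix, n_trees: int, seed: int
) -> DecisivenessEstimate:
    """Monte-Carlo d: sample unrooted binary labeled trees uniformly (taxon
    k+1 inserted onto one of the 2k-3 edges chosen uniformly), score the
    fraction of internal edges with >= 1 decisive locus per tree, and return
    the mean with its standard error over trees."""
    n = coverage.n_taxa
    if n < 4:
        raise ValidationError("partial decisiveness needs at least 4 taxa")
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    masks = coverage.locus_bitmasks()
    rng = np.random.default_rng(seed)
    fractions = np.empty(n_trees)
    for i in range(n_trees):
        tree = _EdgeTree(n)
        for tip in range(3, n):
            tree.attach(tip, int(rng.integers(len(tree.edges))))
        fractions[i] = tree.decisive_edge_fraction(masks)
    d_hat = float(fractions.mean())
    se = float(fractions.std(ddof=1) / math.sqrt(n_trees)) if n_trees > 1 else 0.0
    return DecisivenessEstimate(d_hat=d_hat, se=se, n_trees=n_trees, seed=seed)
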