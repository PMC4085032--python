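"""Synthetic GenBank-like test data.

Generates what the analysis consumes: a binary tree, a concatenated
multi-locus alignment evolved under JC69 with per-locus rate multipliers, a
locus-major missingness pattern with clade-correlated gaps (a few densely
sampled "workhorse" loci and a long sparse tail, emulating the handful of
heavily sequenced plant markers against dozens of rarely sampled ones), a
clade-based taxonomy with a known number of deliberately broken families,
and per-cell sequence records whose deposition years skew earlier for the
well-sampled loci. Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trees_io import (
    Alignment,
    Node,
    PartitionMap,
    Taxonomy,
    Tree,
    ValidationError,
)

__all__ = [
    "LocusSpec",
    "MissingnessScheme",
    "SimConfig",
    "Bundle",
    "simulate_tree",
    "simulate_alignment",
    "apply_missingness",
    "simulate_taxonomy",
    "simulate_record_metadata",
    "simulate_bundle",
    "write_bundle",
    "PRESETS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GAP = ord("-")


@dataclass(frozen=True)
class LocusSpec:
    name: str
    length: int
    rate: float = 1.0

    def __post_init__(self):
        if self.length <= 0:
            raise ValidationError(f"locus {self.name!r}: length must be positive")
        if self.rate < 0:
            raise ValidationError(f"locus {self.name!r}: rate must be >= 0")


@dataclass
class MissingnessScheme:
    """Per-locus retention probabilities q_l plus clade-correlated bias.

    `q` maps locus name -> probability a taxon's cell is kept. For each
    locus, a random subset of the provided clades has its members' keep
    probability multiplied by exp(-clade_bias). When `target_missing` is set
    (a fraction, e.g. 0.96) the probability matrix is rescaled so the
    expected character-wise missingness matches the target; cells are then
    drawn per locus by weighted sampling without replacement at the expected
    count, which pins realized missingness to the target up to rounding.
    """

    q: dict[str, float]
    clade_bias: float = 0.0
    clades: list = field(default_factory=list)  # list of tip-label collections
    biased_clade_prob: float = 0.5
    target_missing: float | None = None

    @classmethod
    def two_component(
        cls,
        loci: list[str],
        n_workhorse: int,
        q_workhorse: float,
        q_tail: float,
        **kwargs,
    ) -> "MissingnessScheme":
        q = {
            name: (q_workhorse if i < n_workhorse else q_tail)
            for i, name in enumerate(loci)
        }
        return cls(q=q, **kwargs)

    def validate(self):
        for name, p in self.q.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"q[{name!r}] = {p} outside [0, 1]")
        if self.clade_bias < 0:
            raise ValidationError("clade_bias must be >= 0")
        return self


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def _scale_to_height(root: Node, height: float):
    depths = []

    def walk(node, d):
        d = d + (node.length or 0.0)
        if node.is_leaf:
            depths.append(d)
        for c in node.children:
            walk(c, d)

    walk(root, 0.0)
    top = max(depths)
    if top <= 0:
        return
    factor = height / top
    for node in root.preorder():
        if node.length is not None:
            node.length *= factor


def simulate_tree(
    n_tips: int,
    model: str = "yule",
    seed: int = 0,
    birth_rate: float = 1.0,
    height: float | None = None,
    label_fmt: str = "g{:04d}",
) -> Tree:
    """Random binary tree with positive branch lengths.

    Yule: exponential waiting times at rate k*birth_rate with a final
    Exp(n*birth_rate) stretch to the present. Coalescent: standard pairwise
    merging with Exp(k choose 2) waits. `height` optionally rescales the
    maximum root-to-tip depth (substitutions/site).
    """
    if n_tips < 4:
        raise ValidationError("need at least 4 tips")
    rng = np.random.default_rng(seed)
    if model == "yule":
        root = Node()
        active: list[tuple[Node, float]] = []
        t = 0.0
        for _ in range(2):
            child = root.add_child(Node())
            active.append((child, t))
        while len(active) < n_tips:
            t += rng.exponential(1.0 / (len(active) * birth_rate))
            idx = int(rng.integers(len(active)))
            node, birth = active.pop(idx)
            node.length = t - birth
            for _ in range(2):
                active.append((node.add_child(Node()), t))
        t += rng.exponential(1.0 / (len(active) * birth_rate))
        for node, birth in active:
            node.length = t - birth
    elif model == "coalescent":
        active = [(Node(), 0.0) for _ in range(n_tips)]
        t = 0.0
        while len(active) > 1:
            k = len(active)
            t += rng.exponential(2.0 / (k * (k - 1)))
            i, j = sorted(rng.choice(k, size=2, replace=False))
            node_j, birth_j = active.pop(int(j))
            node_i, birth_i = active.pop(int(i))
            parent = Node()
            node_i.length = t - birth_i
            node_j.length = t - birth_j
            parent.add_child(node_i)
            parent.add_child(node_j)
            active.append((parent, t))
        root = active[0][0]
    else:
        raise ValidationError(f"unknown tree model {model!r}")

    if height is not None:
        _scale_to_height(root, height)
    leaves = [n for n in root.preorder() if n.is_leaf]
    for i, tip in enumerate(leaves, 1):
        tip.label = label_fmt.format(i)
    return Tree(root)


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def _jc69_evolve(states: np.ndarray, t: float, rng) -> np.ndarray:
    """One JC69 branch: each site changes with probability (3/4)(1-e^(-4t/3)),
    and conditional on change moves uniformly to one of the other 3 bases."""
    if t <= 0:
        return states.copy()
    p_change = 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))
    changed = rng.random(states.shape[0]) < p_change
    shifts = rng.integers(1, 4, size=states.shape[0])
    out = states.copy()
    out[changed] = (states[changed] + shifts[changed]) % 4
    return out


def simulate_alignment(
    tree: Tree, loci: list[LocusSpec], seed: int = 0
) -> tuple[Alignment, PartitionMap]:
    """Site-independent JC69 evolution along the tree, one partition per
    locus with its rate multiplier; partitions exactly tile the alignment."""
    if not loci:
        raise ValidationError("need at least one locus")
    rng = np.random.default_rng(seed)
    tips = tree.tips()
    pieces = {t.label: [] for t in tips}
    intervals: dict[str, list[tuple[int, int]]] = {}
    start = 1
    for locus in loci:
        states: dict[int, np.ndarray] = {}
        for node in tree.root.preorder():
            if node.parent is None:
                states[id(node)] = rng.integers(0, 4, size=locus.length)
            else:
                t = (node.length or 0.0) * locus.rate
                states[id(node)] = _jc69_evolve(states[id(node.parent)], t, rng)
        for tip in tips:
            pieces[tip.label].append(_BASES[states[id(tip)]])
        intervals[locus.name] = [(start, start + locus.length - 1)]
        start += locus.length
    taxa = [t.label for t in tips]
    data = np.vstack([np.concatenate(pieces[name]) for name in taxa])
    return Alignment(taxa, data), PartitionMap(intervals)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------


def apply_missingness(
    alignment: Alignment,
    partitions: PartitionMap,
    scheme: MissingnessScheme,
    seed: int = 0,
) -> tuple[Alignment, dict]:
    """Locus-major, clade-biased cell removal; removed (taxon, locus) cells
    are overwritten with '-'. Returns the thinned alignment and a report with
    the realized character-wise missingness percentage."""
    scheme.validate()
    rng = np.random.default_rng(seed)
    loci = partitions.loci
    lens = np.array([partitions.columns(l).size for l in loci], dtype=float)
    n_taxa = alignment.n_taxa
    taxon_index = {t: i for i, t in enumerate(alignment.taxa)}

    prob = np.tile(np.array([scheme.q[l] for l in loci]), (n_taxa, 1))
    if scheme.clade_bias > 0 and scheme.clades:
        factor = math.exp(-scheme.clade_bias)
        for j in range(len(loci)):
            biased = rng.random(len(scheme.clades)) < scheme.biased_clade_prob
            for clade, hit in zip(scheme.clades, biased):
                if hit:
                    rows = [taxon_index[t] for t in clade if t in taxon_index]
                    prob[rows, j] *= factor

    if scheme.target_missing is not None:
        target_presence = 1.0 - scheme.target_missing
        total_chars = n_taxa * lens.sum()
        for _ in range(4):  # rescale; iterate because clipping at 1 saturates
            expected = float((prob * lens).sum()) / total_chars
            if expected <= 0:
                break
            prob = np.minimum(prob * (target_presence / expected), 1.0)

    keep = np.zeros((n_taxa, len(loci)), dtype=bool)
    for j in range(len(loci)):
        w = prob[:, j]
        pos = np.flatnonzero(w > 0)
        k = min(int(round(float(w.sum()))), pos.size)
        if k > 0:
            # Gumbel top-k = weighted sampling without replacement
            keys = np.log(w[pos]) + rng.gumbel(size=pos.size)
            keep[pos[np.argsort(-keys)[:k]], j] = True

    data = alignment.data.copy()
    for j, locus in enumerate(loci):
        cols = partitions.columns(locus)
        drop = ~keep[:, j]
        if drop.any():
            data[np.ix_(np.flatnonzero(drop), cols)] = _GAP
    if not keep.any():
        warnings.warn("missingness scheme removed every (taxon, locus) cell")
    realized = 100.0 * float((data == _GAP).mean())
    report = {
        "realized_cellwise_missing_pct": realized,
        "target_missing_pct": (
            100.0 * scheme.target_missing if scheme.target_missing is not None else None
        ),
        "kept_cells": int(keep.sum()),
    }
    return Alignment(list(alignment.taxa), data), report


# ---------------------------------------------------------------------------
# taxonomy with ground truth
# ---------------------------------------------------------------------------


def _clade_blocks(tree: Tree, n_families: int) -> list[Node]:
    """Partition the tips into n_families disjoint clades by repeatedly
    splitting the largest current block."""
    sets = tree._leafsets()
    if n_families > tree.n_tips:
        raise ValidationError("more families than tips")
    blocks = [tree.root]
    while len(blocks) < n_families:
        blocks.sort(key=lambda nd: (-len(sets[id(nd)]), min(sets[id(nd)])))
        node = blocks.pop(0)
        if node.is_leaf:
            raise ValidationError("cannot split tips into that many clades")
        blocks.extend(node.children)
    return blocks


def simulate_taxonomy(
    tree: Tree, n_families: int, n_perturbed: int, seed: int = 0
) -> tuple[Taxonomy, pd.DataFrame]:
    """Clade-faithful taxonomy with exactly `n_perturbed` families made
    non-monophyletic.

    Families start as disjoint clades covering all tips. Each perturbed
    family then absorbs one whole child-subtree of an unperturbed donor
    clade's root: the donor remainder is the sibling subtree (still a clade),
    while the receiving family provably is not one (every ancestor of the
    absorbed subtree also contains the donor's remaining tips). The returned
    truth table records the construction.
    """
    if n_perturbed > n_families:
        raise ValidationError("n_perturbed exceeds n_families")
    sets = tree._leafsets()
    rng = np.random.default_rng(seed)
    blocks = sorted(_clade_blocks(tree, n_families), key=lambda nd: min(sets[id(nd)]))
    names = [f"fam{i + 1:03d}" for i in range(n_families)]
    tip_to_family = {}
    for name, node in zip(names, blocks):
        for tip in sets[id(node)]:
            tip_to_family[tip] = name

    perturbed = sorted(
        rng.choice(n_families, size=n_perturbed, replace=False).tolist()
    )
    perturbed_names = {names[i] for i in perturbed}

    donors = [
        i
        for i in range(n_families)
        if names[i] not in perturbed_names and len(sets[id(blocks[i])]) >= 2
    ]
    if len(donors) < n_perturbed:
        raise ValidationError(
            "not enough unperturbed multi-tip donor clades to perturb "
            f"{n_perturbed} families"
        )
    order = rng.permutation(len(donors))
    for fam_idx, donor_pos in zip(perturbed, order):
        donor_root = blocks[donors[donor_pos]]
        moved = min(
            donor_root.children,
            key=lambda c: (len(sets[id(c)]), min(sets[id(c)])),
        )
        for tip in sets[id(moved)]:
            tip_to_family[tip] = names[fam_idx]

    truth = pd.DataFrame(
        {
            "family": names,
            "monophyletic_truth": [names[i] not in perturbed_names for i in range(n_families)],
            "perturbed": [names[i] in perturbed_names for i in range(n_families)],
        }
    )
    taxonomy = Taxonomy({t: t for t in tip_to_family}, tip_to_family)
    return taxonomy, truth


# ---------------------------------------------------------------------------
# record metadata
# ---------------------------------------------------------------------------


def simulate_record_metadata(
    coverage, year_range: tuple[int, int] = (1988, 2012), seed: int = 0
) -> pd.DataFrame:
    """1-3 species-level records per present (taxon, locus) cell, with
    deposition years skewed earlier for the better-sampled loci (the
    long-established markers accumulated their records first)."""
    rng = np.random.default_rng(seed)
    y0, y1 = year_range
    span = y1 - y0
    fracs = coverage.presence.mean(axis=0) if coverage.n_taxa else np.zeros(0)
    lo, hi = (float(fracs.min()), float(fracs.max())) if fracs.size else (0.0, 0.0)
    rows = []
    for i, taxon in enumerate(coverage.taxa):
        for j, locus in enumerate(coverage.loci):
            if not coverage.presence[i, j]:
                continue
            f_norm = 0.5 if hi == lo else (float(fracs[j]) - lo) / (hi - lo)
            for r in range(int(rng.integers(1, 4))):
                u = float(rng.random())
                year = y0 + int(round(span * (u ** (1.0 + 3.0 * f_norm))))
                rows.append(
                    (
                        f"{taxon}_sp{r + 1:02d}",
                        taxon,
                        locus,
                        int(rng.integers(300, 2001)),
                        min(year, y1),
                    )
                )
    return pd.DataFrame(rows, columns=["species", "genus", "locus", "length", "year"])


# ---------------------------------------------------------------------------
# bundles and presets
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    n_tips: int = 200
    tree_model: str = "yule"
    height: float | None = 1.0
    loci: list[LocusSpec] = field(default_factory=list)
    n_workhorse: int = 0
    q_workhorse: float = 1.0
    q_tail: float = 1.0
    clade_bias: float = 0.0
    target_missing: float | None = None
    n_families: int = 10
    n_perturbed: int = 0
    year_range: tuple[int, int] = (1988, 2012)
    seed: int = 0

    def validate(self):
        if self.n_perturbed > self.n_families:
            raise ValidationError("n_perturbed exceeds n_families")
        for q in (self.q_workhorse, self.q_tail):
            if not (0.0 <= q <= 1.0):
                raise ValidationError("sampling probabilities must lie in [0, 1]")
        return self


@dataclass
class Bundle:
    config: SimConfig
    tree: Tree
    alignment: Alignment
    partitions: PartitionMap
    taxonomy: Taxonomy
    truth: pd.DataFrame
    records: pd.DataFrame
    missingness_report: dict


def _mid_clades(tree: Tree, lo: int = 4, frac: float = 0.25) -> list[list[str]]:
    """Mid-sized clades used as the units of clade-correlated missingness."""
    sets = tree._leafsets()
    hi = max(lo + 1, int(tree.n_tips * frac))
    out = []
    for node in tree.root.preorder():
        tips = sets[id(node)]
        if lo <= len(tips) <= hi:
            out.append(sorted(tips))
    return out


def simulate_bundle(config: SimConfig) -> Bundle:
    """Run every generator stage from one master seed."""
    config.validate()
    root_rng = np.random.default_rng(config.seed)
    seeds = {
        name: int(root_rng.integers(2**31))
        for name in ("tree", "alignment", "missingness", "taxonomy", "records")
    }
    tree = simulate_tree(
        config.n_tips, model=config.tree_model, seed=seeds["tree"], height=config.height
    )
    alignment, partitions = simulate_alignment(tree, config.loci, seed=seeds["alignment"])
    scheme = MissingnessScheme.two_component(
        partitions.loci,
        n_workhorse=config.n_workhorse,
        q_workhorse=config.q_workhorse,
        q_tail=config.q_tail,
        clade_bias=config.clade_bias,
        clades=_mid_clades(tree) if config.clade_bias > 0 else [],
        target_missing=config.target_missing,
    )
    alignment, report = apply_missingness(
        alignment, partitions, scheme, seed=seeds["missingness"]
    )
    taxonomy, truth = simulate_taxonomy(
        tree, config.n_families, config.n_perturbed, seed=seeds["taxonomy"]
    )
    from .coverage_decisiveness import build_coverage

    coverage = build_coverage(alignment, partitions)
    records = simulate_record_metadata(
        coverage, year_range=config.year_range, seed=seeds["records"]
    )
    return Bundle(config, tree, alignment, partitions, taxonomy, truth, records, report)


def _default_loci(n_workhorse: int, n_tail: int) -> list[LocusSpec]:
    work_lengths = [1400, 1200, 900, 700, 500]
    work_rates = [0.5, 1.0, 1.5, 2.0, 1.0]
    loci = [
        LocusSpec(f"wh{i + 1:02d}", work_lengths[i % 5], work_rates[i % 5])
        for i in range(n_workhorse)
    ]
    loci += [LocusSpec(f"tail{i + 1:02d}", 500, 1.0) for i in range(n_tail)]
    return loci


def _preset_tiny(seed: int) -> SimConfig:
    return SimConfig(
        n_tips=16,
        height=0.25,
        loci=[LocusSpec(f"loc{i + 1}", 300, 1.0) for i in range(4)],
        n_families=4,
        n_perturbed=0,
        seed=seed,
    )


def _preset_default(seed: int) -> SimConfig:
    return SimConfig(
        n_tips=200,
        height=1.0,
        loci=_default_loci(5, 15),
        n_workhorse=5,
        q_workhorse=0.25,
        q_tail=0.02,
        clade_bias=1.0,
        target_missing=0.96,
        n_families=40,
        n_perturbed=5,
        seed=seed,
    )


def _preset_sparse96(seed: int) -> SimConfig:
    return replace(
        _preset_default(seed),
        loci=_default_loci(5, 35),
        n_workhorse=5,
    )


def _preset_structure32(seed: int) -> SimConfig:
    return SimConfig(
        n_tips=32,
        height=0.25,
        loci=[LocusSpec(f"loc{i + 1:02d}", 500, 1.0) for i in range(10)],
        n_families=8,
        n_perturbed=0,
        seed=seed,
    )


PRESETS = {
    "tiny": _preset_tiny,
    "default": _preset_default,
    "sparse96": _preset_sparse96,
    "structure32": _preset_structure32,
}


def write_bundle(bundle: Bundle, outdir) -> dict:
    """Write the bundle in the exact formats the readers accept; returns the
    path map."""
    import os

    from .trees_io import write_alignment_fasta, write_newick, write_partition_map, write_taxonomy

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "tree": os.path.join(outdir, "tree.nwk"),
        "alignment": os.path.join(outdir, "alignment.fasta"),
        "partitions": os.path.join(outdir, "partitions.txt"),
        "taxonomy": os.path.join(outdir, "taxonomy.tsv"),
        "records": os.path.join(outdir, "records.tsv"),
        "truth": os.path.join(outdir, "family_truth.csv"),
    }
    with open(paths["tree"], "w") as fh:
        fh.write(write_newick(bundle.tree) + "\n")
    write_alignment_fasta(bundle.alignment, paths["alignment"])
    write_partition_map(bundle.partitions, paths["partitions"])
    write_taxonomy(bundle.taxonomy, paths["taxonomy"])
    bundle.records.to_csv(paths["records"], sep="\t", index=False)
    bundle.truth.to_csv(paths["truth"], index=False)
    return paths
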