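"""Trees, alignments, partition maps and tabular metadata: reading and writing.

All coordinate conversion happens here: partition files use the RAxML 1-based
inclusive dialect, everything downstream sees 0-based half-open intervals.
Tip-name matching across inputs is exact string match after whitespace
trimming; mismatches raise with an explicit set difference rather than being
silently dropped.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

__all__ = [
    "Node",
    "Tree",
    "Alignment",
    "PartitionMap",
    "Taxonomy",
    "NewickParseError",
    "ValidationError",
    "parse_newick",
    "write_newick",
    "read_tree",
    "read_alignment",
    "read_partition_map",
    "write_partition_map",
    "read_taxonomy",
    "read_record_metadata",
    "validate_record_metadata",
    "write_figtree_annotations",
]

#: characters that carry no phylogenetic information; partial ambiguity codes
#: (R, Y, S, W, K, M, B, D, H, V) count as data.
MISSING_CHARS = frozenset("-?N")

RECORD_COLUMNS = ["species", "genus", "locus", "length", "year"]


class ValidationError(ValueError):
    pass


class NewickParseError(ValidationError):
    pass


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.|-]+$")


def _quote_label(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


class Node:
    """A node in a rooted tree representation."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label=None, length=None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)


class Tree:
    """Rooted tree container with an unrooted edge view.

    A bifurcating root is retained for display and for rooted analyses
    (monophyly, ancestor ages), but edge-level statistics use the unrooted
    view in which the two root-adjacent edges collapse to one bipartition.
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    def _validate(self):
        labels = [t.label for t in self.tips()]
        if any(lab is None or lab == "" for lab in labels):
            raise ValidationError("all tips must carry non-empty labels")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise ValidationError(f"duplicate tip labels: {sorted(dupes)}")
        for node in self.root.preorder():
            if node.length is not None and node.length < 0:
                raise ValidationError(
                    f"negative branch length {node.length} at {node.label!r}"
                )

    # -- basic accessors ---------------------------------------------------

    def tips(self) -> list[Node]:
        return [n for n in self.root.preorder() if n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    @property
    def has_bifurcating_root(self) -> bool:
        return len(self.root.children) == 2

    def leafset(self, node: Node) -> frozenset:
        return self._leafsets()[id(node)]

    def _leafsets(self) -> dict:
        cached = getattr(self, "_leafset_cache", None)
        if cached is not None:
            return cached
        sets: dict[int, frozenset] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                sets[id(node)] = frozenset([node.label])
            else:
                acc = frozenset()
                for c in node.children:
                    acc |= sets[id(c)]
                sets[id(node)] = acc
        self._leafset_cache = sets
        return sets

    def __getstate__(self):
        # the leafset cache is keyed by node ids, which do not survive pickling
        state = self.__dict__.copy()
        state.pop("_leafset_cache", None)
        return state

    # -- unrooted edge view ------------------------------------------------

    def internal_edges(self) -> list[Node]:
        """Internal edges of the unrooted view, each identified by the child
        node below it. Both sides of each returned edge contain >= 2 tips; at
        a bifurcating root only one of the two equivalent root edges is kept.
        """
        sets = self._leafsets()
        all_tips = sets[id(self.root)]
        edges = []
        skip_second_root_edge = False
        for node in self.root.preorder():
            if node is self.root or node.is_leaf:
                continue
            below = sets[id(node)]
            if len(below) < 2 or len(all_tips - below) < 2:
                continue
            if node.parent is self.root and self.has_bifurcating_root:
                if skip_second_root_edge:
                    continue
                skip_second_root_edge = True
            edges.append(node)
        return edges

    def bipartition(self, edge: Node) -> frozenset:
        """Smaller side of the unrooted bipartition induced by the edge above
        `edge`; ties broken toward the lexicographically smaller label tuple.
        """
        sets = self._leafsets()
        below = sets[id(edge)]
        rest = sets[id(self.root)] - below
        if len(below) < len(rest):
            return below
        if len(rest) < len(below):
            return rest
        return min(below, rest, key=lambda s: tuple(sorted(s)))

    def edge_key(self, edge: Node) -> str:
        """Canonical bipartition string: sorted smaller-side labels, '|'-joined."""
        return "|".join(sorted(self.bipartition(edge)))

    def bipartition_set(self) -> set[frozenset]:
        return {self.bipartition(e) for e in self.internal_edges()}

    def copy(self) -> "Tree":
        return parse_newick(write_newick(self))


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> Tree:
    """Parse a newick string into a :class:`Tree`.

    Underscores in unquoted labels are preserved verbatim. Malformed input
    raises :class:`NewickParseError` carrying position information when the
    underlying parser provides it.
    """
    if not text or not text.strip():
        raise NewickParseError("empty newick string (offset 0)")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        offset = getattr(exc, "col_num", None)
        loc = f" near column {offset}" if offset is not None else ""
        raise NewickParseError(f"malformed newick{loc}: {exc}") from exc

    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return Tree(convert(dtree.seed_node))


def _format_length(x: float) -> str:
    return repr(float(x))


def write_newick(tree: Tree, include_lengths: bool = True) -> str:
    """Deterministic newick output: children ordered by smallest descendant
    tip label; branch lengths written with round-trip precision."""
    sets = tree._leafsets()

    def render(node: Node) -> str:
        if node.is_leaf:
            core = _quote_label(node.label)
        else:
            kids = sorted(node.children, key=lambda c: min(sets[id(c)]))
            core = "(" + ",".join(render(c) for c in kids) + ")"
            if node.label:
                core += _quote_label(str(node.label))
        if include_lengths and node.length is not None:
            core += ":" + _format_length(node.length)
        return core

    return render(tree.root) + ";"


def read_tree(path) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """A concatenated alignment: ordered taxa and an (n_taxa, n_sites) byte
    matrix of uppercase characters ('U' already mapped to 'T')."""

    taxa: list[str]
    data: np.ndarray  # uint8 ASCII codes

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValidationError("alignment matrix shape does not match taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon names in alignment")
        self._index = {t: i for i, t in enumerate(self.taxa)}

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def row(self, taxon: str) -> str:
        return self.data[self._index[taxon]].tobytes().decode("ascii")

    def row_index(self, taxon: str) -> int:
        try:
            return self._index[taxon]
        except KeyError:
            raise ValidationError(f"taxon {taxon!r} not in alignment") from None

    @classmethod
    def from_rows(cls, taxa: list[str], rows: list[str]) -> "Alignment":
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            bad = [t for t, r in zip(taxa, rows) if len(r) != len(rows[0])]
            raise ValidationError(f"ragged alignment rows for taxa: {bad}")
        clean = [r.upper().replace("U", "T") for r in rows]
        arr = (
            np.frombuffer("".join(clean).encode("ascii"), dtype=np.uint8)
            .reshape(len(taxa), -1)
            .copy()
            if taxa
            else np.zeros((0, 0), dtype=np.uint8)
        )
        return cls(list(taxa), arr)

    def data_mask(self, missing_chars=MISSING_CHARS) -> np.ndarray:
        """Boolean matrix: True where the character counts as data."""
        lookup = np.ones(256, dtype=bool)
        for ch in missing_chars:
            lookup[ord(ch)] = False
        return lookup[self.data]


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read a FASTA or relaxed PHYLIP alignment.

    Rows are uppercased and RNA 'U' is mapped to 'T'. Ragged FASTA input
    raises a :class:`ValidationError` naming the offending taxon.
    """
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValidationError(f"no sequences found in {path}")
        taxa = [r.id.strip() for r in records]
        rows = [str(r.seq) for r in records]
        ref = len(rows[0])
        bad = [t for t, r in zip(taxa, rows) if len(r) != ref]
        if bad:
            raise ValidationError(f"ragged alignment rows for taxa: {bad}")
        return Alignment.from_rows(taxa, rows)
    if format in ("relaxed-phylip", "phylip-relaxed", "phylip"):
        msa = AlignIO.read(str(path), "phylip-relaxed")
        return Alignment.from_rows(
            [rec.id.strip() for rec in msa], [str(rec.seq) for rec in msa]
        )
    raise ValueError(f"unknown alignment format {format!r}")


def write_alignment_fasta(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        for taxon in alignment.taxa:
            fh.write(f">{taxon}\n{alignment.row(taxon)}\n")


# ---------------------------------------------------------------------------
# partition maps
# ---------------------------------------------------------------------------

_PARTITION_LINE = re.compile(
    r"^\s*(?P<dtype>[A-Za-z0-9]+)\s*,\s*(?P<name>[^=]+?)\s*=\s*(?P<ranges>.+?)\s*$"
)


@dataclass
class PartitionMap:
    """Locus name -> 1-based inclusive column intervals (RAxML dialect)."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self):
        seen: list[tuple[int, int, str]] = []
        for locus, ivs in self.intervals.items():
            if not ivs:
                raise ValidationError(f"locus {locus!r} has no intervals")
            for a, b in ivs:
                if a < 1 or b < a:
                    raise ValidationError(
                        f"invalid interval {a}-{b} for locus {locus!r}"
                    )
                seen.append((a, b, locus))
        seen.sort()
        for (a1, b1, l1), (a2, b2, l2) in zip(seen, seen[1:]):
            if a2 <= b1:
                raise ValidationError(
                    f"overlapping intervals: {l1!r} {a1}-{b1} and {l2!r} {a2}-{b2}"
                )

    @property
    def loci(self) -> list[str]:
        return list(self.intervals)

    def columns(self, locus: str) -> np.ndarray:
        """0-based column indices for a locus."""
        idx = [np.arange(a - 1, b) for a, b in self.intervals[locus]]
        return np.concatenate(idx)

    def total_span(self) -> int:
        return max(b for ivs in self.intervals.values() for _, b in ivs)

    def check_within(self, n_sites: int):
        if self.total_span() > n_sites:
            raise ValidationError(
                f"partition interval end {self.total_span()} exceeds "
                f"alignment length {n_sites}"
            )


def read_partition_map(path) -> PartitionMap:
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            m = _PARTITION_LINE.match(line)
            if not m:
                raise ValidationError(
                    f"{path}:{lineno}: cannot parse partition line {line!r}"
                )
            name = m.group("name").strip()
            if name in intervals:
                raise ValidationError(f"{path}:{lineno}: duplicate locus {name!r}")
            ivs = []
            for chunk in m.group("ranges").split(","):
                chunk = chunk.strip()
                if "-" in chunk:
                    a, b = chunk.split("-")
                else:
                    a = b = chunk
                ivs.append((int(a), int(b)))
            intervals[name] = ivs
    return PartitionMap(intervals)


def write_partition_map(partitions: PartitionMap, path) -> None:
    with open(path, "w") as fh:
        for locus, ivs in partitions.intervals.items():
            ranges = ", ".join(f"{a}-{b}" for a, b in ivs)
            fh.write(f"DNA, {locus} = {ranges}\n")


# ---------------------------------------------------------------------------
# taxonomy and record metadata tables
# ---------------------------------------------------------------------------


@dataclass
class Taxonomy:
    """Tip -> (genus, family) mapping with the family -> tips view derived."""

    tip_to_genus: dict[str, str]
    tip_to_family: dict[str, str]

    @property
    def families(self) -> dict[str, frozenset]:
        fams: dict[str, set] = {}
        for tip, fam in self.tip_to_family.items():
            fams.setdefault(fam, set()).add(tip)
        return {f: frozenset(s) for f, s in fams.items()}

    def to_frame(self) -> pd.DataFrame:
        tips = sorted(self.tip_to_family)
        return pd.DataFrame(
            {
                "tip": tips,
                "genus": [self.tip_to_genus[t] for t in tips],
                "family": [self.tip_to_family[t] for t in tips],
            }
        )


def read_taxonomy(path) -> Taxonomy:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"tip", "genus", "family"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"taxonomy table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    df["tip"] = df["tip"].str.strip()
    if df["tip"].duplicated().any():
        dupes = sorted(df.loc[df["tip"].duplicated(), "tip"])
        raise ValidationError(f"tips mapped to more than one family: {dupes}")
    return Taxonomy(
        dict(zip(df["tip"], df["genus"].str.strip())),
        dict(zip(df["tip"], df["family"].str.strip())),
    )


def write_taxonomy(taxonomy: Taxonomy, path) -> None:
    taxonomy.to_frame().to_csv(path, sep="\t", index=False)


def read_record_metadata(path, year_range=(1980, 2030)) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_record_metadata(df, year_range=year_range)


def validate_record_metadata(df: pd.DataFrame, year_range=(1980, 2030)) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"record metadata missing columns: {missing}")
    df = df[RECORD_COLUMNS].copy()
    df["length"] = df["length"].astype(int)
    df["year"] = df["year"].astype(int)
    if (df["length"] <= 0).any():
        raise ValidationError("record metadata contains non-positive lengths")
    lo, hi = year_range
    bad = df[(df["year"] < lo) | (df["year"] > hi)]
    if not bad.empty:
        raise ValidationError(
            f"deposition years outside plausible range {year_range}: "
            f"{sorted(bad['year'].unique())}"
        )
    return df


# ---------------------------------------------------------------------------
# FigTree-annotated NEXUS export
# ---------------------------------------------------------------------------


def _palette_colors(values: np.ndarray, palette: str) -> list[str]:
    import matplotlib

    cmap = matplotlib.colormaps[palette]
    vmin, vmax = float(values.min()), float(values.max())
    span = vmax - vmin
    out = []
    for v in values:
        frac = 0.5 if span == 0 else (float(v) - vmin) / span
        r, g, b, _ = cmap(frac)
        out.append(f"#{int(round(r*255)):02x}{int(round(g*255)):02x}{int(round(b*255)):02x}")
    return out


def write_figtree_annotations(
    tree: Tree,
    values: dict[str, float],
    palette: str = "RdYlBu",
    default_color: str = "#808080",
) -> str:
    """Render a NEXUS tree with FigTree `[&!color=#rrggbb]` branch annotations.

    `values` maps canonical bipartition keys (see :meth:`Tree.edge_key`) to
    numbers; they are mapped linearly onto the named matplotlib palette.
    Edges without a value get `default_color`. Non-finite values raise.
    """
    items = sorted(values.items())
    vals = np.array([v for _, v in items], dtype=float)
    if vals.size and not np.all(np.isfinite(vals)):
        bad = [k for k, v in items if not np.isfinite(v)]
        raise ValidationError(f"non-finite annotation values for edges: {bad}")
    colors = dict(zip([k for k, _ in items], _palette_colors(vals, palette))) if vals.size else {}

    edge_color: dict[int, str] = {}
    for edge in tree.internal_edges():
        color = colors.get(tree.edge_key(edge), default_color)
        edge_color[id(edge)] = color
        if edge.parent is tree.root and tree.has_bifurcating_root:
            # the sibling edge is the same unrooted edge; color it identically
            sibling = next(c for c in tree.root.children if c is not edge)
            if not sibling.is_leaf:
                edge_color[id(sibling)] = color

    sets = tree._leafsets()

    def render(node: Node) -> str:
        if node.is_leaf:
            core = _quote_label(node.label)
        else:
            kids = sorted(node.children, key=lambda c: min(sets[id(c)]))
            core = "(" + ",".join(render(c) for c in kids) + ")"
        color = edge_color.get(id(node))
        if color is None and node is not tree.root and not node.is_leaf:
            color = default_color
        if color is not None:
            core += f"[&!color={color}]"
        if node.length is not None:
            core += ":" + _format_length(node.length)
        return core

    taxa = sorted(tree.tip_labels)
    buf = io.StringIO()
    buf.write("#NEXUS\nbegin taxa;\n")
    buf.write(f"\tdimensions ntax={len(taxa)};\n\ttaxlabels\n")
    for t in taxa:
        buf.write(f"\t{_quote_label(t)}\n")
    buf.write(";\nend;\n\nbegin trees;\n")
    buf.write(f"\ttree annotated = [&R] {render(tree.root)};\n")
    buf.write("end;\n")
    return buf.getvalue()
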