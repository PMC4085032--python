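"""Tree annotation analyses: taxonomy monophyly, exemplar selection, and
oldest-exemplar branch ages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees_io import Taxonomy, Tree, ValidationError

__all__ = [
    "MonophylyReport",
    "test_family_monophyly",
    "select_exemplars",
    "oldest_exemplar_age",
]


@dataclass
class MonophylyReport:
    statuses: pd.DataFrame  # columns: family, n_tips, status
    pct_not_rejected: float

    @property
    def n_evaluated(self) -> int:
        return len(self.statuses)


def test_family_monophyly(
    tree: Tree, taxonomy: Taxonomy, rooted: bool = True
) -> MonophylyReport:
    """Monophyly check of each family against the tree.

    A family is ``not_rejected`` when its tips present in the tree are all
    contained in a single clade that contains no other tips; otherwise
    ``rejected``. Families with no tips in the tree are excluded from the
    denominator; a single-tip family is trivially a clade. With
    ``rooted=False`` the test is against the unrooted tree instead: the
    family must be one side of some bipartition (clade status under *some*
    rooting), which is invariant to root placement.
    """
    if not taxonomy.tip_to_family:
        raise ValidationError("empty taxonomy")
    sets = tree._leafsets()
    all_tips = sets[id(tree.root)]
    clades = set(sets.values())
    rows = []
    for family, tips in sorted(taxonomy.families.items()):
        present = frozenset(tips) & all_tips
        if not present:
            continue
        if rooted:
            mono = present in clades
        else:
            mono = present in clades or (all_tips - present) in clades
        rows.append((family, len(present), "not_rejected" if mono else "rejected"))
    if not rows:
        raise ValidationError("no family has tips present in the tree")
    statuses = pd.DataFrame(rows, columns=["family", "n_tips", "status"])
    pct = 100.0 * (statuses["status"] == "not_rejected").mean()
    return MonophylyReport(statuses=statuses, pct_not_rejected=float(pct))


def select_exemplars(records: pd.DataFrame) -> pd.DataFrame:
    """Pick the exemplar record per (genus, locus): the longest sequence for
    any species in the genus; ties broken by earliest deposition year, then
    lexicographic species name."""
    if records.empty:
        raise ValidationError("no records to select exemplars from")
    ordered = records.sort_values(
        ["genus", "locus", "length", "year", "species"],
        ascending=[True, True, False, True, True],
        kind="mergesort",
    )
    return ordered.groupby(["genus", "locus"], sort=True).head(1).reset_index(drop=True)


def oldest_exemplar_age(
    tree: Tree, records: pd.DataFrame, exemplars: pd.DataFrame | None = None
) -> tuple[dict[str, float], dict[str, float]]:
    """Earliest exemplar deposition year per tip and per internal edge of the
    rooted input tree (minimum over the edge's descendant tips).

    Returns ``(tip_years, edge_years)``; tips without exemplar records get
    NaN, and an edge is NaN only if none of its descendants has a record.
    Edge keys are canonical bipartition strings.
    """
    if exemplars is None:
        exemplars = select_exemplars(records)
    per_genus = exemplars.groupby("genus")["year"].min()
    tip_years = {
        tip: float(per_genus.get(tip, np.nan)) for tip in tree.tip_labels
    }
    sets = tree._leafsets()
    edge_years: dict[str, float] = {}
    for edge in tree.internal_edges():
        below = sorted(sets[id(edge)])
        years = [tip_years[t] for t in below if not np.isnan(tip_years[t])]
        edge_years[tree.edge_key(edge)] = float(min(years)) if years else float("nan")
    return tip_years, edge_years
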