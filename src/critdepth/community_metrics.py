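"""Plot-level community response variables.

Computes, per plot and vegetation layer (herb layer = plants up to 1 m height,
tree layer = above 1 m), the responses used downstream: species richness,
Shannon diversity H, Shannon-based evenness E = H / log(S), Faith's
phylogenetic diversity on a rooted dated phylogeny, and stand basal area from
stem diameters.  Herb-layer biomass and plot tree age are field measurements
and enter the response table as given.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "UndefinedDiversityError",
    "UnmatchedTipError",
    "shannon",
    "evenness",
    "richness",
    "faith_pd",
    "basal_area",
    "load_tree",
    "build_response_table",
    "read_response_table",
    "RESPONSE_NAMES",
]

#: The five response variables computed per layer.
RESPONSE_NAMES = ("richness", "shannon", "evenness", "pd", "productivity")


class UndefinedDiversityError(ValueError):
    """Diversity requested on an empty (all-zero) community."""


class UnmatchedTipError(KeyError):
    """Species scored for phylogenetic diversity missing from the tree."""


def _positive(abundances: Sequence[float]) -> np.ndarray:
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("negative abundance")
    return a[a > 0]


def shannon(abundances: Sequence[float], base: float | None = None) -> float:
    """Shannon index H = -sum p_i log p_i over species with positive abundance.

    Natural log by default; pass ``base`` to change it (it cancels in evenness).
    """
    a = _positive(abundances)
    if a.size == 0:
        raise UndefinedDiversityError("all abundances are zero")
    p = a / a.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def richness(abundances: Sequence[float]) -> int:
    """Number of species with positive abundance."""
    a = np.asarray(abundances, dtype=float)
    return int((a > 0).sum())


def evenness(h: float, s: int, base: float | None = None) -> float:
    """Shannon evenness E = H / log(S); defined only for S >= 2."""
    if s <= 0:
        raise UndefinedDiversityError("evenness undefined without species")
    if s == 1:
        raise UndefinedDiversityError("evenness undefined for a single species")
    denom = np.log(s) if base is None else np.log(s) / np.log(base)
    return float(h / denom)


def load_tree(path_or_string: str, schema: str = "newick") -> dendropy.Tree:
    """Read a rooted, branch-length-bearing phylogeny (Newick by default)."""
    if "(" in str(path_or_string):
        tree = dendropy.Tree.get(data=str(path_or_string), schema=schema)
    else:
        tree = dendropy.Tree.get(path=str(path_or_string), schema=schema)
    return tree


def faith_pd(
    tree: dendropy.Tree,
    present: Iterable[str],
    exclusions: Iterable[str] = (),
    include_root: bool = True,
) -> float:
    """Faith's phylogenetic diversity of a species set on a rooted tree.

    Sum of branch lengths of the minimal subtree connecting the retained tips;
    with ``include_root`` (default) the subtree is connected down to the root,
    so a single tip scores its root-to-tip path length.  ``exclusions`` removes
    species (e.g. long-branch outgroups) before scoring.
    """
    retained = set(present) - set(exclusions)
    if not retained:
        raise UndefinedDiversityError("no species retained for PD")
    tip_of = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    unknown = sorted(retained - tip_of.keys())
    if unknown:
        raise UnmatchedTipError(f"species not in tree: {unknown}")

    edges: set[int] = set()
    total = 0.0
    for name in retained:
        node = tip_of[name]
        while node is not None:
            if id(node) in edges:
                break
            edges.add(id(node))
            if node.edge.length:
                total += node.edge.length
            node = node.parent_node
    if not include_root:
        # subtract the path from the root down to the MRCA of the retained
        # tips: the common suffix of all root-paths
        paths = []
        for name in retained:
            node, path = tip_of[name], []
            while node is not None:
                path.append(node)
                node = node.parent_node
            paths.append(path[::-1])
        common = [ns[0] for ns in zip(*paths) if all(n is ns[0] for n in ns)]
        for node in common:
            if node.edge.length:
                total -= node.edge.length
    return total


def basal_area(dbh_values: Sequence[float], min_dbh: float = 10.0) -> float:
    """Plot basal area (m^2): sum of circle areas at breast height.

    Only stems strictly exceeding ``min_dbh`` (cm) count; dbh/200 converts
    diameter in cm to radius in m.
    """
    d = np.asarray(dbh_values, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative DBH")
    d = d[d > min_dbh]
    return float(np.sum(np.pi * (d / 200.0) ** 2))


def build_response_table(
    community: pd.DataFrame,
    tree_age: Mapping[str, float],
    phylogeny: dendropy.Tree | None = None,
    pd_exclusions: Iterable[str] = (),
    dbh: pd.DataFrame | None = None,
    herb_biomass: Mapping[str, float] | None = None,
    log_base: float | None = None,
    pd_root: str = "include",
) -> pd.DataFrame:
    """Assemble the per-(plot, layer) response table from raw inputs.

    ``community`` is long with columns plot_id, layer, species, abundance.
    Tree-layer productivity is basal area from ``dbh`` (plot_id, species,
    dbh_cm); herb-layer productivity is the measured ``herb_biomass``.
    Returns columns plot_id, layer, richness, shannon, evenness, pd,
    productivity, tree_age.
    """
    rows = []
    for (plot, layer), g in community.groupby(["plot_id", "layer"]):
        ab = g.groupby("species")["abundance"].sum()
        ab = ab[ab > 0]
        s = int(ab.size)
        h = shannon(ab.to_numpy(), base=log_base)
        e = evenness(h, s, base=log_base) if s >= 2 else np.nan
        if phylogeny is not None:
            pdiv = faith_pd(
                phylogeny, ab.index, pd_exclusions, include_root=(pd_root == "include")
            )
        else:
            pdiv = np.nan
        if layer == "tree":
            if dbh is None:
                prod = np.nan
            else:
                prod = basal_area(dbh.loc[dbh["plot_id"] == plot, "dbh_cm"].to_numpy())
        else:
            prod = herb_biomass.get(plot, np.nan) if herb_biomass else np.nan
        rows.append((plot, layer, s, h, e, pdiv, prod, tree_age[plot]))
    return pd.DataFrame(
        rows,
        columns=[
            "plot_id", "layer", "richness", "shannon", "evenness", "pd",
            "productivity", "tree_age",
        ],
    )


def read_response_table(path) -> pd.DataFrame:
    """Load a precomputed response table and check its invariants."""
    tab = pd.read_csv(path)
    need = {"plot_id", "layer", *RESPONSE_NAMES, "tree_age"}
    missing = need - set(tab.columns)
    if missing:
        raise ValueError(f"response table lacks columns {sorted(missing)}")
    if (tab["tree_age"] <= 0).any():
        raise ValueError("tree age must be positive")
    for col in ("richness", "shannon", "pd", "productivity"):
        if (tab[col].dropna() < 0).any():
            raise ValueError(f"{col} must be non-negative")
    return tab
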