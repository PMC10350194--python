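"""Multi-set membership partitioning (supervenn backbone), cross-genotype
direction concordance, and complete-linkage clustering for heatmap ordering."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from trap_rescue.errors import ConfigError, DataError


def membership_partition(sets) -> pd.DataFrame:
    """Partition the union of k named sets by membership pattern.

    ``sets`` is a mapping name -> gene set, or an iterable of (name, set)
    pairs (duplicate names are rejected).  Every gene in the union lands in
    exactly one pattern row; all 2^k - 1 non-empty patterns are reported,
    empty ones with count 0.  Rows are ordered by descending count then
    lexicographic pattern string (a '1' marks membership in the
    corresponding set, in input order).
    """
    pairs = list(sets.items()) if hasattr(sets, "items") else list(sets)
    names = [n for n, _s in pairs]
    if len(names) != len(set(names)):
        raise ConfigError("duplicate set names")
    k = len(names)
    if k < 1:
        raise ConfigError("need at least one set")
    members = {n: set(s) for n, s in pairs}
    union = sorted(set().union(*members.values())) if members else []
    by_pattern: dict[str, list[str]] = {}
    for g in union:
        pattern = "".join("1" if g in members[n] else "0" for n in names)
        by_pattern.setdefault(pattern, []).append(g)
    rows = []
    for i in range(1, 2**k):
        pattern = format(i, f"0{k}b")
        genes = by_pattern.get(pattern, [])
        rows.append((pattern, len(genes), ",".join(genes)))
    table = pd.DataFrame(rows, columns=["pattern", "count", "genes"])
    table = table.sort_values(
        ["count", "pattern"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table.attrs["set_names"] = names
    return table


def direction_concordance(
    basal_direction: dict[str, pd.Series], log2fc: dict[str, pd.Series]
) -> dict[str, list[str]]:
    """Bucket genes basal-significant in *all* genotypes by their sign pattern.

    Returns ``all_up``, ``all_down``, and one ``opposing_<genotype>`` bucket
    per genotype naming the odd-one-out (possible for three genotypes, where
    any mixed pattern is a 2-vs-1 split).
    """
    names = list(basal_direction)
    dirs = pd.DataFrame({g: basal_direction[g] for g in names})
    sig_all = dirs.isin(["up", "down"]).all(axis=1)
    out: dict[str, list[str]] = {"all_up": [], "all_down": []}
    for g in names:
        out[f"opposing_{g}"] = []
    for gene in dirs.index[sig_all]:
        signs = dirs.loc[gene, names]
        ups = [g for g in names if signs[g] == "up"]
        if len(ups) == len(names):
            out["all_up"].append(gene)
        elif not ups:
            out["all_down"].append(gene)
        else:
            minority = ups if len(ups) * 2 < len(names) else [g for g in names if signs[g] == "down"]
            if len(minority) == 1:
                out[f"opposing_{minority[0]}"].append(gene)
            else:  # k > 3 can split 2-2; bucket by the up-set
                out.setdefault("opposing_" + "+".join(sorted(ups)), []).append(gene)
    return out


def hcluster_complete(matrix: pd.DataFrame) -> np.ndarray:
    """Agglomerative clustering, Euclidean distance, complete linkage.

    Missing values are imputed as 0 with a warning (genes absent from one
    contrast's table).  Returns the scipy linkage matrix; merge heights are
    non-decreasing (complete linkage admits no inversions).
    """
    if len(matrix) < 2:
        raise DataError("clustering needs at least 2 rows")
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        warnings.warn("missing values imputed as 0 before clustering", stacklevel=2)
        x = np.nan_to_num(x)
    return hierarchy.linkage(x, method="complete", metric="euclidean")


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return walk(tree, tree.dist) + ";"
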