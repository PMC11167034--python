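"""Within-clone B-cell dendrograms from mutation-derived features.

Feature vectors are (v_identity, j_identity, v_shm, j_shm, vj_shm_rate) per
cell; trees use Euclidean distances with the classical 'ward.D' update rule
applied to the distances as given (no pre-squaring, distinguishing it from
ward.D2), and are serialized to Newick with merge heights as branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

FEATURES = ["v_identity", "j_identity", "v_shm", "j_shm", "vj_shm_rate"]


def lineage_features(shm_records: pd.DataFrame, zscore: bool = False) -> pd.DataFrame:
    """Per-cell feature matrix for one clone (index cell_id, columns FEATURES).

    Raises for clones of fewer than 2 cells (no tree is built for them).
    Features are used raw by default; ``zscore`` standardizes columns.
    """
    if len(shm_records) < 2:
        raise ValueError("lineage features require a clone of at least 2 cells")
    feats = shm_records.set_index("cell_id")[FEATURES].astype(float)
    if zscore:
        sd = feats.std(ddof=0).replace(0.0, 1.0)
        feats = (feats - feats.mean()) / sd
    return feats


@dataclass
class LineageTree:
    clone_id: str
    leaves: list
    merges: list  # (left_node, right_node, height); nodes are leaf names or merge indices
    newick: str


def _ward_d_agglomerate(dist: np.ndarray, labels: list[str]):
    """Agglomeration with the ward.D Lance-Williams update on raw distances.

    Ties in the minimum inter-cluster distance break on the lexicographically
    smallest (min cell id) pair, making the result invariant to input order.
    """
    n = len(labels)
    active = {i: {"size": 1, "node": labels[i], "min_label": labels[i]} for i in range(n)}
    d = {(min(i, j), max(i, j)): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    heights = {}
    while len(active) > 1:
        best = None
        for (i, j), val in d.items():
            key = (val, *sorted((active[i]["min_label"], active[j]["min_label"])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        h = d[(min(i, j), max(i, j))]
        ni, nj = active[i]["size"], active[j]["size"]
        merges.append((active[i]["node"], active[j]["node"], h))
        new = {
            "size": ni + nj,
            "node": len(merges) - 1,
            "min_label": min(active[i]["min_label"], active[j]["min_label"]),
        }
        heights[len(merges) - 1] = h
        for k in list(active):
            if k in (i, j):
                continue
            nk = active[k]["size"]
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            dij = h
            t = ni + nj + nk
            d[(min(k, next_id), max(k, next_id))] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * dij
            ) / t
        for key in [key for key in d if i in key or j in key]:
            del d[key]
        del active[i], active[j]
        active[next_id] = new
        next_id += 1
    return merges


def build_tree(features: pd.DataFrame, clone_id: str = "") -> LineageTree:
    """Ward.D dendrogram over Euclidean feature distances, with Newick output."""
    if len(features) < 2:
        raise ValueError("need at least 2 feature vectors")
    bad = features.index[~np.isfinite(features.to_numpy()).all(axis=1)]
    if len(bad):
        raise ValueError(f"non-finite features for cells: {list(bad)}")
    labels = [str(i) for i in features.index]
    dist = squareform(pdist(features.to_numpy(dtype=float), metric="euclidean"))
    merges = _ward_d_agglomerate(dist, labels)

    heights = {i: h for i, (_, _, h) in enumerate(merges)}

    def height_of(node):
        return 0.0 if isinstance(node, str) else heights[node]

    def render(node, parent_height):
        if isinstance(node, str):
            return f"{node}:{parent_height:.10g}"
        left, right, h = merges[node]
        return (f"({render(left, h)},{render(right, h)})"
                f":{max(parent_height - h, 0.0):.10g}")

    left, right, h = merges[-1]
    newick = f"({render(left, h)},{render(right, h)}):0;"
    return LineageTree(clone_id=clone_id, leaves=labels, merges=merges, newick=newick)


def parse_newick(newick: str):
    """Round-trip helper: leaf names and root-to-leaf depths from Newick text."""
    from skbio import TreeNode

    tree = TreeNode.read(StringIO(newick))
    depths = {}
    for tip in tree.tips():
        depths[tip.name] = tip.accumulate_to_ancestor(tree)
    return tree, depths


def build_clone_trees(
    shm_records: pd.DataFrame, clones, min_size: int = 2, zscore: bool = False
) -> dict[str, LineageTree]:
    """Trees for every clone of at least ``min_size`` cells with SHM records."""
    clone_of = clones.clone_of()
    records = shm_records[shm_records["cell_id"].isin(clone_of.index)].copy()
    records["clone_id"] = clone_of.loc[records["cell_id"]].to_numpy()
    trees = {}
    for cid, grp in records.groupby("clone_id", sort=True):
        if len(grp) < max(min_size, 2):
            continue
        feats = lineage_features(grp.drop(columns="clone_id"), zscore=zscore)
        trees[cid] = build_tree(feats, clone_id=cid)
    return trees
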