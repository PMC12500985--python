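"""Agglomerative clustering of genotypes with dendrogram-scale utilities.

The agglomeration is written out explicitly (rather than delegated) so the
tie-break is fully deterministic and independent of input row order: among
equidistant cluster pairs, the pair whose sorted genotype-name tuples compare
lexicographically smallest merges first.  Complete ("furthest neighbour") and
unweighted average ("between groups") linkage are supported, both on
Euclidean distances, and both monotone so dendrogram heights never invert.

Dendrogram heights are also reported on the 0–25 "rescaled distance" scale
used by legacy stats GUIs (largest merge ↦ 25, proportional below).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = ["ClusterGrouping", "cluster_genotypes", "heatmap_matrix"]

LINKAGES = ("complete", "average")

RESCALE_MAX = 25.0


@dataclass
class ClusterGrouping:
    genotypes: list[str]
    merges: list[tuple[tuple[int, ...], tuple[int, ...], float]]  # leaf-index sets + raw height
    linkage_matrix: np.ndarray  # scipy-style (G-1, 4)
    heights: np.ndarray  # raw merge heights, length G-1
    rescaled_heights: np.ndarray  # 0–25 scale
    leaf_order: list[int]  # dendrogram left-to-right leaf order
    labels: np.ndarray  # group id per genotype, 1..k, input order
    k: int

    def labels_by_name(self) -> dict[str, int]:
        return {g: int(l) for g, l in zip(self.genotypes, self.labels)}

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, l in zip(self.genotypes, self.labels):
            out.setdefault(int(l), []).append(g)
        return out

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"genotype": self.genotypes, "group": self.labels})

    def to_newick(self, path: str | Path | None = None) -> str:
        """Newick string with rescaled heights as node depths.

        Leaf branch lengths span from height 0 up to the first merge.
        """
        G = len(self.genotypes)
        node_height = {i: 0.0 for i in range(G)}
        node_repr = {i: self.genotypes[i] for i in range(G)}
        for t, (a, b, _h) in enumerate(self.merges):
            h = self.rescaled_heights[t]
            ia, ib = int(self.linkage_matrix[t, 0]), int(self.linkage_matrix[t, 1])
            parts = []
            for child in (ia, ib):
                bl = h - node_height[child]
                parts.append(f"{node_repr[child]}:{bl:.6g}")
            nid = G + t
            node_repr[nid] = f"({parts[0]},{parts[1]})"
            node_height[nid] = h
        newick = node_repr[G + len(self.merges) - 1] + ";" if self.merges else f"({self.genotypes[0]});"
        if path is not None:
            Path(path).write_text(newick + "\n", encoding="utf-8")
        return newick


def _pairwise(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def _cluster_distance(
    leaves_a: tuple[int, ...], leaves_b: tuple[int, ...], D: np.ndarray, linkage: str
) -> float:
    block = D[np.ix_(leaves_a, leaves_b)]
    return float(block.max() if linkage == "complete" else block.mean())


def _agglomerate(
    D: np.ndarray, names: Sequence[str], linkage: str
) -> tuple[list, np.ndarray, list[int]]:
    """Run the full merge sequence; returns (merges, linkage_matrix, leaf_order)."""
    G = D.shape[0]
    # active cluster: id -> (leaves tuple, ordered leaves for display)
    active: dict[int, tuple[tuple[int, ...], list[int]]] = {
        i: ((i,), [i]) for i in range(G)
    }
    merges = []
    Z = np.zeros((G - 1, 4))
    next_id = G
    for t in range(G - 1):
        best = None
        for ia in active:
            for ib in active:
                if ia >= ib:
                    continue
                la, _ = active[ia]
                lb, _ = active[ib]
                d = _cluster_distance(la, lb, D, linkage)
                ka = tuple(sorted(names[i] for i in la))
                kb = tuple(sorted(names[i] for i in lb))
                if ka > kb:
                    ka, kb, ia2, ib2 = kb, ka, ib, ia
                else:
                    ia2, ib2 = ia, ib
                cand = (d, ka, kb, ia2, ib2)
                if best is None or cand < best:
                    best = cand
        d, _, _, ia, ib = best
        la, oa = active.pop(ia)
        lb, ob = active.pop(ib)
        merges.append((la, lb, d))
        Z[t] = (ia, ib, d, len(la) + len(lb))
        active[next_id] = (tuple(sorted(la + lb)), oa + ob)
        next_id += 1
    leaf_order = next(iter(active.values()))[1] if active else []
    return merges, Z, leaf_order


def _labels_at(
    merges: list, G: int, *, k: int | None, height: np.ndarray, threshold: float | None
) -> tuple[np.ndarray, int]:
    """Replay merges up to a k- or height-defined cut and label groups."""
    parent = list(range(G))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    n_clusters = G
    for t, (la, lb, _d) in enumerate(merges):
        if k is not None and n_clusters <= k:
            break
        if threshold is not None and height[t] > threshold:
            break
        ra, rb = find(la[0]), find(lb[0])
        parent[rb] = ra
        n_clusters -= 1
    roots: dict[int, int] = {}
    labels = np.zeros(G, dtype=int)
    for i in range(G):  # number groups by first appearance in input order
        r = find(i)
        labels[i] = roots.setdefault(r, len(roots) + 1)
    return labels, len(roots)


def cluster_genotypes(
    X: pd.DataFrame | np.ndarray,
    genotypes: Sequence[str] | None = None,
    *,
    linkage: str = "complete",
    k: int | None = 3,
    rescaled_height: float | None = None,
) -> ClusterGrouping:
    """Cluster genotypes on Euclidean distances and cut into groups.

    Cut either at ``k`` groups (default 3) or, if ``rescaled_height`` is
    given, at a threshold on the 0–25 rescaled dendrogram distance.
    """
    if linkage not in LINKAGES:
        raise ParameterError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if isinstance(X, pd.DataFrame):
        if genotypes is None:
            genotypes = [str(i) for i in X.index]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if genotypes is None:
            genotypes = [f"G{i+1}" for i in range(arr.shape[0])]
    G = arr.shape[0]
    if G < 2:
        raise ParameterError(f"need at least 2 genotypes, got {G}")
    if not np.all(np.isfinite(arr)):
        raise ParameterError("features must be finite")
    if rescaled_height is None:
        if k is None or not 1 <= k <= G:
            raise ParameterError(f"k must be in [1, {G}], got {k}")

    D = _pairwise(arr)
    merges, Z, leaf_order = _agglomerate(D, list(genotypes), linkage)
    heights = np.array([m[2] for m in merges])
    hmax = heights.max() if len(heights) else 0.0
    rescaled = RESCALE_MAX * heights / hmax if hmax > 0 else np.zeros_like(heights)

    if rescaled_height is not None:
        labels, k_eff = _labels_at(
            merges, G, k=None, height=rescaled, threshold=rescaled_height
        )
    else:
        labels, k_eff = _labels_at(merges, G, k=k, height=rescaled, threshold=None)

    return ClusterGrouping(
        genotypes=list(genotypes),
        merges=merges,
        linkage_matrix=Z,
        heights=heights,
        rescaled_heights=rescaled,
        leaf_order=leaf_order,
        labels=labels,
        k=k_eff,
    )


def heatmap_matrix(
    X: pd.DataFrame,
    *,
    linkage: str = "complete",
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Row-standardized index × genotype matrix plus dendrogram orders.

    Input is genotype × index; the output is transposed (one row per index),
    each row scaled to mean 0, sample SD 1 across genotypes.  Constant rows
    become zeros with a warning.  Returns (matrix, row_order, column_order)
    where the orders are clustering leaf orders over indices and genotypes.
    """
    M = X.T.astype(float)  # index × genotype
    arr = M.to_numpy()
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        names = [str(M.index[i]) for i in np.flatnonzero(flat)]
        warnings.warn(f"constant row(s) standardized to zero: {names}", stacklevel=2)
        sd[flat] = 1.0
    std = (arr - mean) / sd
    std[flat] = 0.0
    out = pd.DataFrame(std, index=M.index, columns=M.columns)

    row_cl = cluster_genotypes(out, [str(i) for i in out.index], linkage=linkage, k=1)
    col_cl = cluster_genotypes(
        out.T, [str(c) for c in out.columns], linkage=linkage, k=1
    )
    row_order = [str(out.index[i]) for i in row_cl.leaf_order]
    col_order = [str(out.columns[i]) for i in col_cl.leaf_order]
    return out, row_order, col_order
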