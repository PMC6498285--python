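"""Portrait similarity, minimum spanning tree, and zoom-in retraining.

Individuals are compared through Pearson correlation of their portrait
vectors (meta-SNP level).  The MST is built on dissimilarity 1 - r with
deterministic lexicographic tie-breaking, so reruns are bit-stable.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genotype_io import AlleleMatrix
from .portrayal import Portrait, mean_portrait, portrait_stack
from .som import SomConfig, SomModel, centralize, train_som
from .spots import SpotSet, segment_spots, summary_map

__all__ = [
    "SimilarityMatrix",
    "MstTree",
    "correlation_matrix",
    "build_mst",
    "zoom_in",
    "ZoomResult",
]


@dataclasses.dataclass
class SimilarityMatrix:
    values: np.ndarray  # M x M Pearson correlations
    ids: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("similarity matrix shape does not match id list")


@dataclasses.dataclass
class MstTree:
    nodes: pd.DataFrame  # sample_id (+ population/region when known)
    edges: list[tuple[str, str, float]]
    total_weight: float

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for _, row in self.nodes.iterrows():
            g.add_node(row["sample_id"], **{k: row[k] for k in self.nodes.columns if k != "sample_id"})
        for i, j, w in self.edges:
            g.add_edge(i, j, weight=w)
        return g

    def write_edges(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("node_i\tnode_j\tweight\n")
            for i, j, w in self.edges:
                fh.write(f"{i}\t{j}\t{w:.17g}\n")

    def write_gml(self, path: str | os.PathLike) -> None:
        nx.write_gml(self.to_networkx(), path)

    def render(self, path: str | os.PathLike, color_by: str = "region", seed: int = 0) -> None:
        """Spring-layout PNG with nodes colored by a metadata column."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        g = self.to_networkx()
        pos = nx.spring_layout(g, seed=seed, weight=None)
        labels = (
            self.nodes.set_index("sample_id")[color_by]
            if color_by in self.nodes.columns
            else pd.Series("all", index=self.nodes["sample_id"])
        )
        palette = plt.get_cmap("tab10")
        groups = sorted(labels.unique())
        colors = [palette(groups.index(labels[n]) % 10) for n in g.nodes]
        fig, ax = plt.subplots(figsize=(8, 8))
        nx.draw_networkx(g, pos=pos, ax=ax, node_color=colors, node_size=60, with_labels=False)
        handles = [
            plt.Line2D([], [], marker="o", ls="", color=palette(k % 10), label=grp)
            for k, grp in enumerate(groups)
        ]
        ax.legend(handles=handles, loc="best", fontsize=8)
        ax.set_axis_off()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def correlation_matrix(portraits: Sequence[Portrait]) -> SimilarityMatrix:
    """Pairwise Pearson correlation of flattened portrait grids."""
    if len(portraits) < 2:
        raise ValueError("need at least two portraits")
    shape = portraits[0].grid.shape
    for p in portraits:
        if p.grid.shape != shape:
            raise ValueError("portrait grid shapes differ")
    flat = np.array([p.flat for p in portraits])
    sd = flat.std(axis=1)
    for p, s in zip(portraits, sd):
        if s == 0:
            raise ValueError(f"portrait of '{p.subject}' is constant; correlation undefined")
    values = np.corrcoef(flat)
    return SimilarityMatrix(values=values, ids=[p.subject for p in portraits])


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_mst(sim: SimilarityMatrix, sample_meta: pd.DataFrame | None = None) -> MstTree:
    """Kruskal MST on dissimilarity 1 - r.

    Edges of equal weight are taken in lexicographic node-pair order, making
    the tree deterministic.
    """
    w = 1.0 - sim.values
    if not np.isfinite(w).all():
        raise ValueError("similarity matrix contains non-finite values")
    m = len(sim.ids)
    edges = sorted(
        (float(w[i, j]), i, j) for i in range(m) for j in range(i + 1, m)
    )
    uf = _UnionFind(m)
    chosen: list[tuple[str, str, float]] = []
    total = 0.0
    for weight, i, j in edges:
        if uf.union(i, j):
            chosen.append((sim.ids[i], sim.ids[j], weight))
            total += weight
            if len(chosen) == m - 1:
                break
    if sample_meta is not None:
        nodes = sample_meta[sample_meta["sample_id"].isin(sim.ids)].reset_index(drop=True)
    else:
        nodes = pd.DataFrame({"sample_id": sim.ids})
    return MstTree(nodes=nodes, edges=chosen, total_weight=total)


@dataclasses.dataclass
class ZoomResult:
    model: SomModel
    matrix: AlleleMatrix  # column-restricted matrix the model was trained on
    portraits: dict[str, Portrait]
    mean_portraits: dict[str, Portrait]
    spots: SpotSet


def zoom_in(
    matrix: AlleleMatrix,
    samples: Sequence[str],
    config: SomConfig,
    grouping: str = "population",
    threshold_quantile: float = 0.90,
    min_units: int = 5,
    refilter_maf: float | None = None,
) -> ZoomResult:
    """Retrain the SOM on a sample subset and rerun portrayal + segmentation.

    Profiles are re-centralized on the subset.  The globally filtered SNP
    set is reused as-is unless ``refilter_maf`` is given, in which case the
    MAF filter is re-applied on the subset frequencies.
    """
    samples = list(dict.fromkeys(samples))
    if len(samples) < 2:
        raise ValueError("zoom-in needs at least 2 samples")
    all_ids = list(matrix.sample_ids)
    unknown = [s for s in samples if s not in all_ids]
    if unknown:
        raise KeyError(f"unknown sample(s): {unknown[:5]}")
    cols = np.array([all_ids.index(s) for s in samples])
    sub = matrix.take_samples(cols)
    if refilter_maf is not None:
        from .genotype_io import filter_by_maf

        sub = filter_by_maf(sub, refilter_maf)
    centered, means = centralize(sub)
    model = train_som(centered, config, row_means=means)
    portraits = portrait_stack(model, sub)
    groups = sub.sample_meta.groupby(grouping)["sample_id"].apply(list)
    mean_portraits = {
        grp: mean_portrait([portraits[s] for s in ids], subject=grp)
        for grp, ids in groups.items()
    }
    smap = summary_map(list(mean_portraits.values()))
    spots = segment_spots(
        smap, model, sub.snp_ids, threshold_quantile=threshold_quantile, min_units=min_units
    )
    return ZoomResult(
        model=model, matrix=sub, portraits=portraits, mean_portraits=mean_portraits, spots=spots
    )
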