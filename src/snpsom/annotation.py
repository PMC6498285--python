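"""SNP-disease association catalogs and ontology level mapping.

Association lists from several tabular sources are unioned and
deduplicated.  Disease terms are mapped onto the level-3 stratum of a
disease ontology (minimum is_a depth 3 from the root); deeper terms map to
all of their level-3 ancestors, shallower terms are kept as-is and flagged.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from collections import deque
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "OntologyGraph",
    "AssociationCatalog",
    "parse_obo",
    "write_obo",
    "compute_depths",
    "map_to_level3",
    "load_associations",
]

log = logging.getLogger(__name__)

ANALYSIS_LEVEL = 3


@dataclasses.dataclass
class OntologyGraph:
    """Rooted is_a ontology with minimum-depth levels.

    ``parents`` maps each term to its is_a parents.  ``depth`` (filled by
    :func:`compute_depths`) is the minimum edge count from the root;
    ``unreachable`` collects terms with no path from the root.
    """

    terms: dict[str, str]
    parents: dict[str, tuple[str, ...]]
    root: str
    depth: dict[str, int] = dataclasses.field(default_factory=dict)
    unreachable: set[str] = dataclasses.field(default_factory=set)

    def children(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {t: [] for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                out.setdefault(p, []).append(child)
        return out

    def ancestors_at_depth(self, term: str, level: int) -> set[str]:
        """All ancestors of ``term`` (inclusive) whose depth equals ``level``."""
        found: set[str] = set()
        seen: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            if self.depth.get(t) == level:
                found.add(t)
            stack.extend(self.parents.get(t, ()))
        return found


def parse_obo(path: str | os.PathLike, root: str | None = None) -> OntologyGraph:
    """Parse a flat OBO file (term id, name and is_a lines only)."""
    terms: dict[str, str] = {}
    parents: dict[str, list[str]] = {}
    cur: str | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line == "[Term]":
                cur = None
            elif line.startswith("id:") and cur is None:
                cur = line[3:].strip()
                terms.setdefault(cur, cur)
                parents.setdefault(cur, [])
            elif line.startswith("name:") and cur is not None:
                terms[cur] = line[5:].strip()
            elif line.startswith("is_a:") and cur is not None:
                target = line[5:].strip().split("!")[0].strip()
                parents[cur].append(target)
    for ps in parents.values():
        for p in ps:
            terms.setdefault(p, p)
            parents.setdefault(p, [])
    if root is None:
        roots = sorted(t for t, ps in parents.items() if not ps)
        if len(roots) != 1:
            raise ValueError(
                f"ontology has {len(roots)} parentless terms ({roots[:5]}...); "
                "pass an explicit root"
            )
        root = roots[0]
    graph = OntologyGraph(
        terms=terms, parents={t: tuple(ps) for t, ps in parents.items()}, root=root
    )
    return compute_depths(graph)


def write_obo(graph: OntologyGraph, path: str | os.PathLike) -> None:
    """Serialize an :class:`OntologyGraph` back to minimal OBO text."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(graph.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {graph.terms[term]}\n")
            for parent in graph.parents.get(term, ()):
                fh.write(f"is_a: {parent} ! {graph.terms.get(parent, parent)}\n")


def compute_depths(graph: OntologyGraph) -> OntologyGraph:
    """Breadth-first minimum depth from the root; flags unreachable terms.

    Raises on a cyclic is_a structure, listing one offending cycle.
    """
    dag = nx.DiGraph()
    dag.add_nodes_from(graph.terms)
    for child, ps in graph.parents.items():
        for p in ps:
            dag.add_edge(child, p)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValueError(f"ontology is_a graph contains a cycle: {cycle}")
    depth = {graph.root: 0}
    children = graph.children()
    queue = deque([graph.root])
    while queue:
        term = queue.popleft()
        for child in children.get(term, ()):
            if child not in depth:
                depth[child] = depth[term] + 1
                queue.append(child)
    unreachable = set(graph.terms) - set(depth)
    if unreachable:
        log.warning("%d ontology term(s) unreachable from root %s", len(unreachable), graph.root)
    return dataclasses.replace(graph, depth=depth, unreachable=unreachable)


def map_to_level3(term: str, graph: OntologyGraph) -> set[str]:
    """Level-3 analysis term(s) for ``term``.

    Depth > 3 maps to all level-3 ancestors; depth 3 maps to itself; depth
    < 3 maps to itself (the caller should treat it as shallow).  Unknown or
    unreachable terms yield the empty set.
    """
    if not graph.depth:
        raise ValueError("depths not computed; call compute_depths first")
    d = graph.depth.get(term)
    if d is None:
        return set()
    if d <= ANALYSIS_LEVEL:
        return {term}
    return graph.ancestors_at_depth(term, ANALYSIS_LEVEL)


@dataclasses.dataclass
class AssociationCatalog:
    """Deduplicated SNP-disease associations with optional gene links.

    ``records`` has columns snp_id, term_id, gene, source with unique
    (snp_id, term_id) pairs.  After :meth:`map_terms`, ``level3`` holds the
    exploded snp_id / level3_term table and ``unmapped`` / ``shallow`` flag
    the terms that could not be, or were not, lifted to level 3.
    """

    records: pd.DataFrame
    level3: pd.DataFrame | None = None
    unmapped: set[str] = dataclasses.field(default_factory=set)
    shallow: set[str] = dataclasses.field(default_factory=set)

    def __post_init__(self) -> None:
        self.records = (
            self.records.drop_duplicates(subset=["snp_id", "term_id"])
            .reset_index(drop=True)
        )

    def snp_ids(self) -> set[str]:
        return set(self.records["snp_id"])

    def gene_map(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        sub = self.records.dropna(subset=["gene"])
        for snp, gene in zip(sub["snp_id"], sub["gene"]):
            out.setdefault(snp, set()).add(gene)
        return out

    def map_terms(self, graph: OntologyGraph) -> "AssociationCatalog":
        """Attach level-3 analysis terms to every record."""
        rows = []
        unmapped: set[str] = set()
        shallow: set[str] = set()
        for snp, term in zip(self.records["snp_id"], self.records["term_id"]):
            targets = map_to_level3(term, graph)
            if not targets:
                unmapped.add(term)
                continue
            if graph.depth.get(term, ANALYSIS_LEVEL) < ANALYSIS_LEVEL:
                shallow.add(term)
            for t in sorted(targets):
                rows.append((snp, t))
        level3 = pd.DataFrame(rows, columns=["snp_id", "level3_term"]).drop_duplicates()
        if unmapped:
            log.warning("%d disease term(s) could not be mapped to level 3", len(unmapped))
        return AssociationCatalog(
            records=self.records, level3=level3, unmapped=unmapped, shallow=shallow
        )

    def term_to_snps(self, universe: Iterable[str] | None = None) -> dict[str, set[str]]:
        """Level-3 term -> annotated SNP set, optionally restricted to a universe."""
        if self.level3 is None:
            raise ValueError("catalog terms not mapped; call map_terms first")
        keep = None if universe is None else set(universe)
        out: dict[str, set[str]] = {}
        for snp, term in zip(self.level3["snp_id"], self.level3["level3_term"]):
            if keep is None or snp in keep:
                out.setdefault(term, set()).add(snp)
        return out


def load_associations(paths: Sequence[str | os.PathLike]) -> AssociationCatalog:
    """Union tabular association files, dropping duplicate (snp, term) pairs.

    Each file needs columns snp_id and disease_term_id; gene and source are
    optional.
    """
    frames = []
    for path in paths:
        table = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("snp_id", "disease_term_id"):
            if col not in table.columns:
                raise ValueError(f"association file {path} lacks required column '{col}'")
        frame = pd.DataFrame(
            {
                "snp_id": table["snp_id"],
                "term_id": table["disease_term_id"],
                "gene": table["gene"] if "gene" in table.columns else pd.NA,
                "source": table["source"] if "source" in table.columns else str(path),
            }
        )
        log.info("load_associations: %s contributes %d record(s)", path, len(frame))
        frames.append(frame)
    records = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["snp_id", "term_id", "gene", "source"])
    )
    return AssociationCatalog(records=records)
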