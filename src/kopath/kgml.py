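"""Signed directed gene-interaction graphs parsed from KGML pathway files.

KGML (KEGG Markup Language) describes a pathway as ``entry`` elements
(genes, compounds, groups, maps) joined by ``relation`` elements whose
``subtype`` carries the interaction semantics (activation, inhibition,
phosphorylation, ...).  This module parses such files into
:class:`PathwayGraph` objects, merges a collection of them into a
:class:`GlobalGraph` (the union of all known gene-gene interactions), and
builds the per-pathway signed, out-degree-normalised adjacency matrices used
by perturbation propagation.

Gene identity is the organism-prefixed Entrez string (``"mmu:17874"``)
throughout; mapping from probe or symbol space is the caller's job.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from lxml import etree

__all__ = [
    "KGMLError",
    "KGMLParseError",
    "KGMLStructureError",
    "UnknownRelationError",
    "InteractionEdge",
    "PathwayGraph",
    "GlobalGraph",
    "BetaMatrices",
    "DEFAULT_RELATION_SIGNS",
    "DEFAULT_BETA",
    "split_gene_id",
    "parse_kgml",
    "load_collection",
    "build_global_graph",
    "pathway_beta_matrices",
    "to_networkx",
    "write_graphml",
    "write_edge_list",
    "read_edge_list",
]


class KGMLError(ValueError):
    """Base class for KGML parsing problems."""


class KGMLParseError(KGMLError):
    """The file is not well-formed XML."""


class KGMLStructureError(KGMLError):
    """Well-formed XML that violates KGML structure (e.g. dangling entry id)."""


class UnknownRelationError(KGMLError):
    """A relation subtype absent from the configured sign/weight mapping."""


# Relation subtype -> sign of the interaction.  Activating chemistry is +1,
# inhibitory chemistry is -1; relations without a clear direction of effect
# (binding, indirect effect, state change, ...) stay in the graph for edge
# scoring but carry sign 0 and are excluded from perturbation propagation.
DEFAULT_RELATION_SIGNS: dict[str, int] = {
    "activation": 1,
    "expression": 1,
    "phosphorylation": 1,
    "inhibition": -1,
    "repression": -1,
    "dephosphorylation": -1,
    "binding/association": 0,
    "indirect effect": 0,
    "state change": 0,
    "dissociation": 0,
    "ubiquitination": 0,
    "methylation": 0,
    "glycosylation": 0,
    "missing interaction": 0,
    "compound": 0,
    "hidden compound": 0,
}

#: Relation subtype -> signed weight beta used in the perturbation model.
DEFAULT_BETA: dict[str, float] = {
    rel: float(sign) for rel, sign in DEFAULT_RELATION_SIGNS.items()
}


def split_gene_id(gene_id: str) -> tuple[str, int]:
    """Split an organism-prefixed Entrez id into ``(prefix, number)``.

    >>> split_gene_id("mmu:17874")
    ('mmu', 17874)
    """
    prefix, _, num = gene_id.partition(":")
    if not prefix or not num:
        raise ValueError(f"not an organism-prefixed gene id: {gene_id!r}")
    return prefix, int(num)


@dataclass(frozen=True)
class InteractionEdge:
    """One signed directed gene-gene interaction."""

    source: str
    target: str
    relation: str
    sign: int
    pathway_ids: frozenset[str] = frozenset()

    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.relation)


@dataclass(frozen=True)
class PathwayGraph:
    """A single pathway: its gene set and signed directed interactions."""

    pathway_id: str
    name: str
    organism: str
    genes: frozenset[str]
    edges: tuple[InteractionEdge, ...]
    warning: str | None = None

    @property
    def psize(self) -> int:
        """Number of genes in the pathway (the pSize used downstream)."""
        return len(self.genes)


@dataclass(frozen=True)
class GlobalGraph:
    """The union graph over a pathway collection.

    Directed edges are deduplicated on (source, target, relation), each
    recording every contributing pathway; ``undirected_edge_keys`` collapses
    (X, Y) and (Y, X) into one unordered pair for symmetric edge scoring.
    """

    genes: frozenset[str]
    edges: tuple[InteractionEdge, ...]
    undirected_edge_keys: frozenset[tuple[str, str]]


def _relation_sign(
    relation: str, signs: Mapping[str, int], strict: bool, context: str
) -> int:
    if relation in signs:
        return signs[relation]
    if strict:
        raise UnknownRelationError(
            f"unknown relation subtype {relation!r} in {context}"
        )
    warnings.warn(
        f"unknown relation subtype {relation!r} in {context}; using sign 0",
        stacklevel=3,
    )
    return 0


def parse_kgml(
    path: str | Path,
    *,
    relation_signs: Mapping[str, int] | None = None,
    strict: bool = False,
) -> PathwayGraph:
    """Parse one KGML file into a :class:`PathwayGraph`.

    Group entries are expanded to their member genes with relations copied
    to every member; entries holding several gene ids are expanded so each
    constituent gene receives the entry's relations; self-edges created by
    expansion are dropped, as are relations touching non-gene entries.
    """
    path = Path(path)
    signs = dict(relation_signs or DEFAULT_RELATION_SIGNS)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise KGMLParseError(f"malformed KGML file {path}: {exc}") from exc
    root = tree.getroot()
    pathway_id = (root.get("name") or path.stem).removeprefix("path:")
    title = root.get("title") or pathway_id
    organism = root.get("org") or ""

    entry_ids: set[str] = set()
    entry_genes: dict[str, tuple[str, ...]] = {}
    group_members: dict[str, list[str]] = {}
    for entry in root.findall("entry"):
        eid = entry.get("id")
        if eid is None:
            raise KGMLStructureError(f"entry without id in {path}")
        entry_ids.add(eid)
        etype = entry.get("type")
        if etype == "gene":
            entry_genes[eid] = tuple((entry.get("name") or "").split())
        elif etype == "group":
            group_members[eid] = [
                c.get("id") for c in entry.findall("component") if c.get("id")
            ]

    # Expand groups to the union of their member entries' genes.
    for gid, members in group_members.items():
        genes: list[str] = []
        for member in members:
            if member not in entry_ids:
                raise KGMLStructureError(
                    f"group entry {gid} references missing entry {member} in {path}"
                )
            genes.extend(entry_genes.get(member, ()))
        entry_genes[gid] = tuple(dict.fromkeys(genes))

    genes_present: set[str] = set()
    for eid, genes in entry_genes.items():
        if eid not in group_members:  # group members already counted
            genes_present.update(genes)

    warning = None
    if not genes_present:
        warning = "no gene entries"
        warnings.warn(f"{path}: pathway has no gene entries", stacklevel=2)

    edge_map: dict[tuple[str, str, str], int] = {}
    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        for eid in (e1, e2):
            if eid not in entry_ids:
                raise KGMLStructureError(
                    f"relation references missing entry id {eid} in {path}"
                )
        src_genes = entry_genes.get(e1, ())
        tgt_genes = entry_genes.get(e2, ())
        if not src_genes or not tgt_genes:
            continue  # relation touching a dropped (non-gene) entry
        subtypes = [s.get("name") for s in rel.findall("subtype") if s.get("name")]
        if not subtypes:
            subtypes = ["unknown"]
        for subtype in subtypes:
            sign = _relation_sign(subtype, signs, strict, str(path))
            for src in src_genes:
                for tgt in tgt_genes:
                    if src == tgt:
                        continue
                    edge_map.setdefault((src, tgt, subtype), sign)

    edges = tuple(
        InteractionEdge(s, t, r, sign, frozenset({pathway_id}))
        for (s, t, r), sign in sorted(edge_map.items())
    )
    return PathwayGraph(
        pathway_id=pathway_id,
        name=title,
        organism=organism,
        genes=frozenset(genes_present),
        edges=edges,
        warning=warning,
    )


def load_collection(directory: str | Path, **kwargs) -> list[PathwayGraph]:
    """Parse every pathway listed in a collection directory's manifest.

    The manifest (``manifest.json``) maps pathway ids to KGML file names;
    without a manifest every ``*.xml`` file in the directory is parsed.
    """
    directory = Path(directory)
    manifest = directory / "manifest.json"
    if manifest.exists():
        meta = json.loads(manifest.read_text())
        files = [directory / rec["file"] for rec in meta["pathways"].values()]
    else:
        files = sorted(directory.glob("*.xml"))
    return [parse_kgml(f, **kwargs) for f in files]


def build_global_graph(pathways: Sequence[PathwayGraph]) -> GlobalGraph:
    """Union a pathway collection into the deduplicated global graph."""
    if not pathways:
        raise ValueError("at least one pathway is required")
    genes: set[str] = set()
    merged: dict[tuple[str, str, str], tuple[int, frozenset[str]]] = {}
    for pw in pathways:
        genes.update(pw.genes)
        for e in pw.edges:
            key = e.key()
            if key in merged:
                sign, pids = merged[key]
                merged[key] = (sign, pids | e.pathway_ids)
            else:
                merged[key] = (e.sign, e.pathway_ids)
    edges = tuple(
        InteractionEdge(s, t, r, sign, pids)
        for (s, t, r), (sign, pids) in sorted(merged.items())
    )
    undirected = frozenset(
        (min(e.source, e.target), max(e.source, e.target)) for e in edges
    )
    return GlobalGraph(
        genes=frozenset(genes), edges=edges, undirected_edge_keys=undirected
    )


@dataclass(frozen=True)
class BetaMatrices:
    """Per-pathway signed adjacency matrices for perturbation propagation.

    ``per_relation[rel][i, j]`` holds the raw weight beta(rel) for each edge
    gene_j -> gene_i of that relation class.  ``combined`` is the summed
    matrix with every column u divided by N_ds(u), the number of distinct
    downstream targets of u (so each source's total outgoing weight
    magnitude is conserved at |beta|).
    """

    genes: tuple[str, ...]
    per_relation: Mapping[str, np.ndarray]
    combined: np.ndarray

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


def pathway_beta_matrices(
    pathway: PathwayGraph,
    beta_map: Mapping[str, float] | None = None,
    *,
    strict: bool = False,
) -> BetaMatrices:
    """Build the normalised signed adjacency matrix B for one pathway."""
    betas = dict(beta_map or DEFAULT_BETA)
    genes = tuple(sorted(pathway.genes))
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    per_relation: dict[str, np.ndarray] = {}
    raw = np.zeros((n, n))
    for e in pathway.edges:
        if e.relation not in betas:
            if strict:
                raise UnknownRelationError(
                    f"no beta weight for relation {e.relation!r} "
                    f"in pathway {pathway.pathway_id}"
                )
            warnings.warn(
                f"no beta weight for relation {e.relation!r}; using 0",
                stacklevel=2,
            )
            beta = 0.0
        else:
            beta = betas[e.relation]
        mat = per_relation.setdefault(e.relation, np.zeros((n, n)))
        i, j = idx[e.target], idx[e.source]
        mat[i, j] = beta
        raw[i, j] += beta
    n_ds = (raw != 0).sum(axis=0).astype(float)  # distinct weighted targets per source
    with np.errstate(invalid="ignore", divide="ignore"):
        combined = np.where(n_ds > 0, raw / n_ds, 0.0)
    return BetaMatrices(genes=genes, per_relation=per_relation, combined=combined)


# ---------------------------------------------------------------------------
# graph export / import


def to_networkx(graph: PathwayGraph | GlobalGraph) -> nx.MultiDiGraph:
    """Convert to a networkx MultiDiGraph (one edge per relation class)."""
    g = nx.MultiDiGraph()
    g.add_nodes_from(sorted(graph.genes))
    for e in graph.edges:
        g.add_edge(
            e.source,
            e.target,
            relation=e.relation,
            sign=e.sign,
            pathway_ids=",".join(sorted(e.pathway_ids)),
        )
    return g


def write_graphml(graph: PathwayGraph | GlobalGraph | nx.Graph, path: str | Path) -> None:
    g = graph if isinstance(graph, nx.Graph) else to_networkx(graph)
    nx.write_graphml(g, str(path))


def write_edge_list(graph: PathwayGraph | GlobalGraph, path: str | Path) -> None:
    """Write the tab-delimited edge-list format (round-trippable)."""
    lines = []
    if isinstance(graph, PathwayGraph):
        lines.append(f"# pathway_id\t{graph.pathway_id}")
        lines.append(f"# name\t{graph.name}")
        lines.append(f"# organism\t{graph.organism}")
    lines.append("# genes\t" + ",".join(sorted(graph.genes)))
    lines.append("source\ttarget\trelation\tsign\tpathway_ids")
    for e in sorted(graph.edges, key=InteractionEdge.key):
        lines.append(
            f"{e.source}\t{e.target}\t{e.relation}\t{e.sign}\t"
            + ",".join(sorted(e.pathway_ids))
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path) -> PathwayGraph | GlobalGraph:
    """Read the edge-list format written by :func:`write_edge_list`."""
    meta: dict[str, str] = {}
    genes: frozenset[str] = frozenset()
    edges: list[InteractionEdge] = []
    header_seen = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("\t")
            if key == "genes":
                genes = frozenset(g for g in value.split(",") if g)
            else:
                meta[key] = value
            continue
        if not header_seen:
            header_seen = True  # column header line
            continue
        src, tgt, rel, sign, pids = line.split("\t")
        edges.append(
            InteractionEdge(
                src, tgt, rel, int(sign), frozenset(pids.split(",")) - {""}
            )
        )
    edge_tuple = tuple(sorted(edges, key=InteractionEdge.key))
    if "pathway_id" in meta:
        return PathwayGraph(
            pathway_id=meta["pathway_id"],
            name=meta.get("name", meta["pathway_id"]),
            organism=meta.get("organism", ""),
            genes=genes,
            edges=edge_tuple,
        )
    undirected = frozenset(
        (min(e.source, e.target), max(e.source, e.target)) for e in edge_tuple
    )
    return GlobalGraph(genes=genes, edges=edge_tuple, undirected_edge_keys=undirected)
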