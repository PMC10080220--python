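"""Synthetic pathway collections and knockout expression datasets.

The generator emulates the study design this package analyses: a
collection of KEGG-style pathways (written as valid KGML so the regular
parser consumes them) in which a designated knockout gene appears in a
known subset of pathways, plus a two-group log2 expression matrix in which
the knockout's differential signal propagates outward along global-graph
edges.  Expression is modelled as a per-gene Normal(8, 1) baseline with
iid Normal(0, noise_sd) measurement noise; in knockout samples each gene
at hop distance d from the KO gene shifts by -effect * decay^d * s, where
s is the product of edge signs along the discovery path (d = 0 at the KO
gene itself, so the knockout lowers its own transcript by `effect` log2
units and propagates a decayed, sign-flipped echo through the network).

All randomness flows from the single mandatory seed, so repeated runs are
byte-identical.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .expression import ExpressionDataset
from .kgml import GlobalGraph, InteractionEdge, PathwayGraph, build_global_graph

__all__ = [
    "FixtureSpec",
    "build_collection",
    "write_collection",
    "generate_pathway_collection",
    "simulate_ko_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic knockout study.

    Defaults describe a small but structured study: 30 pathways of 8-25
    genes drawn from a 500-gene universe (large enough that pathway
    overlap stays modest, as in real curated collections), 70% of the
    pathways containing the KO gene, a 5-vs-5 two-group design, a 2.0
    log2-unit knockout effect that decays by half per network hop, and
    0.5 log2 units of measurement noise.
    """

    seed: int
    n_pathways: int = 30
    size_range: tuple[int, int] = (8, 25)
    ko_fraction: float = 0.7
    edge_density: float = 0.08
    n_per_group: int = 5
    effect: float = 2.0
    decay: float = 0.5
    noise_sd: float = 0.5
    universe_size: int = 500
    organism: str = "syn"

    def __post_init__(self) -> None:
        if self.size_range[0] < 2:
            raise ValueError("pathway size must be at least 2")
        if not 0 < self.ko_fraction < 1:
            raise ValueError("ko_fraction must be in (0, 1)")
        if self.n_pathways < 1 or self.n_per_group < 2:
            raise ValueError("need >= 1 pathway and >= 2 samples per group")
        if not 0 <= self.decay <= 1:
            raise ValueError("decay must be in [0, 1]")
        if self.noise_sd < 0 or self.effect < 0:
            raise ValueError("effect and noise_sd must be non-negative")

    @property
    def ko_gene(self) -> str:
        return f"{self.organism}:1"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["size_range"] = list(self.size_range)
        return d


def build_collection(spec: FixtureSpec) -> list[PathwayGraph]:
    """Generate the in-memory pathway collection for a fixture spec.

    Each pathway is a feed-forward cascade: a random recursive tree
    oriented away from its root plus feed-forward extra edges added with
    probability ``edge_density`` per remaining gene pair, relations drawn
    from {activation, inhibition} (70/30).  Exactly
    round(ko_fraction * n_pathways) pathways contain the KO gene, rooted
    at it (the knockout models an upstream adapter); genes shared with
    the KO cascades occupy downstream positions elsewhere (shared genes
    in curated collections are predominantly effector modules).
    """
    rng = np.random.default_rng(spec.seed)
    universe = [f"{spec.organism}:{i}" for i in range(1, spec.universe_size + 1)]
    others = universe[1:]
    n_ko = round(spec.ko_fraction * spec.n_pathways)
    ko_flags = np.zeros(spec.n_pathways, bool)
    ko_flags[rng.permutation(spec.n_pathways)[:n_ko]] = True

    pathways = []
    lo, hi = spec.size_range
    ko_pool: set[str] = set()  # genes appearing in KO-containing pathways
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_pathways)]
    # draw KO-containing pathways first so the shared-effector pool exists
    # when non-KO pathways are built; emit in index order afterwards
    build_order = sorted(range(spec.n_pathways), key=lambda i: not ko_flags[i])
    drawn: dict[int, list[str]] = {}
    for i in build_order:
        size = sizes[i]
        if ko_flags[i]:
            members = [spec.ko_gene] + list(
                rng.choice(others, size=size - 1, replace=False)
            )
            ko_pool.update(members)
        else:
            members = list(rng.choice(others, size=size, replace=False))
        drawn[i] = members
    for i in range(spec.n_pathways):
        size = sizes[i]
        members = drawn[i]
        # Cascade topology: a random recursive tree rooted at order[0],
        # every edge oriented away from the root, plus feed-forward extra
        # edges (earlier -> later in attachment order).  Signaling
        # pathways are cascades, and the resulting DAG keeps the
        # perturbation system I - B nonsingular.  The KO gene models an
        # upstream adapter/receptor-proximal regulator, so in pathways
        # that contain it, it is the cascade root.
        order = list(rng.permutation(members))
        if ko_flags[i]:
            order.remove(spec.ko_gene)
            order.insert(0, spec.ko_gene)
        else:
            # Genes shared with the KO-gene cascades model common effector
            # modules (cytokines, transcription-factor outputs), which sit
            # at the downstream end of the pathways that reuse them.
            shared = [g for g in order if g in ko_pool]
            own = [g for g in order if g not in ko_pool]
            order = own + shared
        pair_set: set[tuple[str, str]] = set()
        edges: list[tuple[str, str]] = []
        for j in range(1, size):
            parent = order[int(rng.integers(0, j))]
            child = order[j]
            edges.append((parent, child))
            pair_set.add((min(parent, child), max(parent, child)))
        for j in range(size):
            for k in range(j + 1, size):
                a, b = order[j], order[k]
                key = (min(a, b), max(a, b))
                if key in pair_set:
                    continue
                if rng.random() < spec.edge_density:
                    edges.append((a, b))
                    pair_set.add(key)
        pid = f"{spec.organism}{i + 1:05d}"
        edge_objs = []
        for src, tgt in edges:
            relation = "activation" if rng.random() < 0.7 else "inhibition"
            sign = 1 if relation == "activation" else -1
            edge_objs.append(
                InteractionEdge(src, tgt, relation, sign, frozenset({pid}))
            )
        pathways.append(
            PathwayGraph(
                pathway_id=pid,
                name=f"synthetic pathway {i + 1}",
                organism=spec.organism,
                genes=frozenset(members),
                edges=tuple(sorted(edge_objs, key=InteractionEdge.key)),
            )
        )
    return pathways


def _pathway_to_kgml(pw: PathwayGraph) -> bytes:
    root = etree.Element(
        "pathway",
        name=f"path:{pw.pathway_id}",
        org=pw.organism,
        number=pw.pathway_id.removeprefix(pw.organism),
        title=pw.name,
    )
    gene_entry = {}
    for i, gene in enumerate(sorted(pw.genes), start=1):
        gene_entry[gene] = str(i)
        etree.SubElement(root, "entry", id=str(i), name=gene, type="gene")
    for e in sorted(pw.edges, key=InteractionEdge.key):
        rel = etree.SubElement(
            root,
            "relation",
            entry1=gene_entry[e.source],
            entry2=gene_entry[e.target],
            type="PPrel",
        )
        arrow = "-->" if e.sign >= 0 else "--|"
        etree.SubElement(rel, "subtype", name=e.relation, value=arrow)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def write_collection(
    pathways: list[PathwayGraph], outdir: str | Path, spec: FixtureSpec
) -> Path:
    """Write KGML files plus a manifest recording per-pathway bookkeeping."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "ko_gene": spec.ko_gene,
        "seed": spec.seed,
        "spec": spec.to_dict(),
        "pathways": {},
    }
    for pw in pathways:
        fname = f"{pw.pathway_id}.xml"
        (outdir / fname).write_bytes(_pathway_to_kgml(pw))
        manifest["pathways"][pw.pathway_id] = {
            "file": fname,
            "n_genes": pw.psize,
            "n_edges": len(pw.edges),
            "contains_ko": spec.ko_gene in pw.genes,
        }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return outdir


def generate_pathway_collection(
    spec: FixtureSpec, outdir: str | Path
) -> tuple[list[PathwayGraph], Path]:
    """Generate and write a collection; returns the graphs and directory."""
    pathways = build_collection(spec)
    return pathways, write_collection(pathways, outdir, spec)


def _signed_hop_distances(
    graph: GlobalGraph, source: str
) -> dict[str, tuple[int, int]]:
    """BFS hop distance and first-path edge-sign product from the source.

    Propagation follows edge direction (knockout effects flow downstream
    in signaling semantics); zero-sign edges do not propagate.  Neighbor
    visitation is sorted for determinism.
    """
    adj: dict[str, list[tuple[str, int]]] = {}
    for e in graph.edges:
        if e.sign == 0:
            continue
        adj.setdefault(e.source, []).append((e.target, e.sign))
    for k in adj:
        adj[k] = sorted(set(adj[k]))
    out = {source: (0, 1)}
    queue = deque([source])
    while queue:
        g = queue.popleft()
        d, s = out[g]
        for nbr, sign in adj.get(g, ()):
            if nbr not in out:
                out[nbr] = (d + 1, s * sign)
                queue.append(nbr)
    return out


def simulate_ko_dataset(
    spec: FixtureSpec, pathways: list[PathwayGraph]
) -> ExpressionDataset:
    """Simulate the two-group expression matrix for a fixture collection.

    The measured gene universe is the union of pathway genes.  Knockout
    samples shift each reachable gene by -effect * decay^d * signprod as
    described in the module docstring; unreachable genes carry pure noise.
    """
    if not any(spec.ko_gene in pw.genes for pw in pathways):
        raise ValueError(f"KO gene {spec.ko_gene} absent from the collection")
    graph = build_global_graph(pathways)
    genes = sorted(graph.genes)
    rng = np.random.default_rng([spec.seed, 1])

    hops = _signed_hop_distances(graph, spec.ko_gene)
    shift = np.zeros(len(genes))
    for i, g in enumerate(genes):
        if g in hops:
            d, s = hops[g]
            shift[i] = -spec.effect * (spec.decay**d if d else 1.0) * s

    n = spec.n_per_group
    ko_cols = [f"KO_{j + 1}" for j in range(n)]
    ct_cols = [f"CTRL_{j + 1}" for j in range(n)]
    baseline = rng.normal(8.0, 1.0, size=len(genes))
    noise = rng.normal(0.0, spec.noise_sd, size=(len(genes), 2 * n))
    data = baseline[:, None] + noise
    data[:, :n] += shift[:, None]
    matrix = pd.DataFrame(data, index=genes, columns=ko_cols + ct_cols)
    groups = pd.Series(
        ["KO"] * n + ["CTRL"] * n, index=ko_cols + ct_cols
    )
    return ExpressionDataset(
        matrix=matrix,
        groups=groups,
        ko_genes=frozenset({spec.ko_gene}),
        dataset_id=f"sim_seed{spec.seed}",
    )


def write_dataset(dataset: ExpressionDataset, outdir: str | Path) -> Path:
    """Write matrix.tsv, design.tsv and dataset.json in the pipeline formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.matrix.to_csv(outdir / "matrix.tsv", sep="\t", index_label="gene")
    pd.DataFrame(
        {"sample": dataset.groups.index, "group": dataset.groups.values}
    ).to_csv(outdir / "design.tsv", sep="\t", index=False)
    (outdir / "dataset.json").write_text(
        json.dumps(
            {
                "dataset_id": dataset.dataset_id,
                "ko_genes": sorted(dataset.ko_genes),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return outdir
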