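"""Network pharmacology: ADME filtering, layered networks, target ranking.

The compound-target-metabolite network is assembled from three file-based
layers — a bipartite compound-target table, a protein-protein interactome
expanded one hop around seed proteins, and a bipartite gene-metabolite
association table — merged on upper-cased gene symbols.  Candidate targets
(the intersection of compound targets with the protein side of the
metabolite layers) are ranked by the R score

    R = 0.5 * (A_i - A_min) / (A_max - A_min)
      + 0.5 * (1/B_j - min 1/B) / (max 1/B - min 1/B)

where A_i is a node's average shortest path length (hops, within its
component) and B_j its betweenness centrality normalised to [0, 1].  Both
terms are min-max normalised over the candidate set, so the candidate
holding both the minimal A and the maximal B scores exactly 0; lower R
means a more central, better-connected target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AdmeCompound",
    "LayeredNetwork",
    "CentralityRow",
    "TargetScore",
    "adme_filter",
    "read_adme_table",
    "gene_metabolite_network",
    "expand_ppi",
    "compound_target_network",
    "merge_tripartite",
    "node_centralities",
    "r_score",
    "rank_targets",
    "read_edge_list",
    "write_sif",
    "write_graphml",
]

LAYERS = ("compound", "target", "adjacent_protein", "pathway_gene", "metabolite")


@dataclass
class AdmeCompound:
    compound_id: str
    name: str
    ob: float  # oral bioavailability, %
    dl: float  # drug-likeness, unitless

    def __post_init__(self) -> None:
        if self.ob < 0 or self.dl < 0:
            raise ValueError(f"{self.compound_id}: OB and DL must be non-negative")


@dataclass
class LayeredNetwork:
    """Simple undirected graph whose nodes carry exactly one layer tag."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_node(self, node: str, layer: str) -> None:
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        existing = self.graph.nodes.get(node, {}).get("layer")
        if existing is not None and existing != layer:
            raise ValueError(f"conflicting layer tags for node {node!r}: "
                             f"{existing!r} vs {layer!r}")
        self.graph.add_node(node, layer=layer)

    def add_edge(self, a: str, b: str, source: str = "") -> None:
        if a == b:
            return  # simple graph: no self-loops
        self.graph.add_edge(a, b, source=source)

    def nodes_in_layer(self, layer: str) -> set:
        return {n for n, d in self.graph.nodes(data=True) if d.get("layer") == layer}


def read_adme_table(path) -> list[AdmeCompound]:
    df = pd.read_csv(path, sep="\t")
    return [
        AdmeCompound(str(r.compound_id), str(r.name), float(r.ob), float(r.dl))
        for r in df.itertuples()
    ]


def adme_filter(
    compounds: list[AdmeCompound],
    ob_min: float = 30.0,
    dl_min: float = 0.18,
    whitelist: set | None = None,
) -> tuple[set, dict]:
    """ADME screen: keep compounds with OB >= ob_min and DL >= dl_min.

    A whitelist of ids to retain regardless of the thresholds (literature
    evidence) is unioned in; the report distinguishes rule-passing from
    whitelist-only members and surfaces any overlap between the two, since
    a whitelisted compound may also pass the rule.
    """
    if ob_min < 0 or dl_min < 0:
        raise ValueError("thresholds must be non-negative")
    whitelist = set(whitelist or ())
    ids = {c.compound_id for c in compounds}
    unknown = whitelist - ids
    if unknown:
        raise ValueError(f"whitelist ids absent from ADME table: {sorted(unknown)}")
    by_rule = {c.compound_id for c in compounds if c.ob >= ob_min and c.dl >= dl_min}
    selected = by_rule | whitelist
    report = {
        "pass_by_rule": sorted(by_rule),
        "whitelist_only": sorted(whitelist - by_rule),
        "overlap": sorted(whitelist & by_rule),
        "n_selected": len(selected),
    }
    return selected, report


def gene_metabolite_network(metabolites: list[str], associations) -> LayeredNetwork:
    """Bipartite metabolite-gene graph from an association table.

    ``associations`` is an iterable of (metabolite_id, gene_symbol) pairs
    (e.g. read from a two-column TSV).  Metabolites with no association stay
    as isolated nodes so they remain visible in the merged network.
    """
    net = LayeredNetwork()
    for m in metabolites:
        net.add_node(str(m), "metabolite")
    isolated = set(map(str, metabolites))
    for met, gene in associations:
        met, gene = str(met), str(gene).upper()
        if met not in net.graph:
            net.add_node(met, "metabolite")
        net.add_node(gene, "pathway_gene")
        net.add_edge(met, gene, source="gene_metabolite")
        isolated.discard(met)
    if isolated:
        warnings.warn(f"metabolites without gene associations: {sorted(isolated)}")
    return net


def expand_ppi(seeds: set, interactome) -> LayeredNetwork:
    """One-hop expansion of seed proteins in a PPI edge list.

    Returns the subgraph induced on the seeds plus their direct neighbours;
    neighbours are tagged ``adjacent_protein``.  Seeds missing from the
    interactome are kept isolated with a warning.
    """
    g = nx.Graph()
    for a, b in interactome:
        a, b = str(a).upper(), str(b).upper()
        if a != b:
            g.add_edge(a, b)
    seeds = {str(s).upper() for s in seeds}
    net = LayeredNetwork()
    for s in seeds:
        net.add_node(s, "pathway_gene")
    missing = seeds - set(g)
    if missing:
        warnings.warn(f"seeds absent from interactome: {sorted(missing)}")
    keep = set(seeds & set(g))
    for s in seeds & set(g):
        keep |= set(g.neighbors(s))
    for n in keep - seeds:
        net.add_node(n, "adjacent_protein")
    for a, b in g.subgraph(keep).edges():
        net.add_edge(a, b, source="ppi")
    return net


def compound_target_network(compounds: set, targets) -> LayeredNetwork:
    """Bipartite compound-target graph restricted to a compound set.

    ``targets`` is an iterable of (compound_id, target_symbol) pairs.  The
    target set is reported as the union over the retained compounds via
    :meth:`LayeredNetwork.nodes_in_layer`.
    """
    compounds = set(map(str, compounds))
    net = LayeredNetwork()
    for c in sorted(compounds):
        net.add_node(c, "compound")
    for comp, tgt in targets:
        comp, tgt = str(comp), str(tgt).upper()
        if comp not in compounds:
            continue
        net.add_node(tgt, "target")
        net.add_edge(comp, tgt, source="compound_target")
    return net


def merge_tripartite(
    ct: LayeredNetwork,
    ppi: LayeredNetwork,
    gm: LayeredNetwork,
    disease_genes: set | None = None,
) -> tuple[LayeredNetwork, set]:
    """Union the three layers and extract the candidate-target intersection.

    The intersection set is (targets of the compound-target layer) ∩
    (protein/gene nodes of the PPI and gene-metabolite layers).  Nodes in
    the intersection are re-tagged ``target`` in the merged graph; other
    layer tags must agree across inputs or an error lists the offenders.
    ``disease_genes`` marks target nodes with a ``disease`` attribute.
    """
    ct_targets = ct.nodes_in_layer("target")
    protein_nodes = (
        ppi.nodes_in_layer("pathway_gene")
        | ppi.nodes_in_layer("adjacent_protein")
        | gm.nodes_in_layer("pathway_gene")
    )
    intersection = ct_targets & protein_nodes

    merged = LayeredNetwork()
    conflicts = []
    for net in (ct, ppi, gm):
        for n, d in net.graph.nodes(data=True):
            layer = "target" if n in intersection else d["layer"]
            try:
                merged.add_node(n, layer)
            except ValueError:
                conflicts.append(n)
    if conflicts:
        raise ValueError(f"conflicting layer tags for nodes: {sorted(set(conflicts))}")
    for net in (ct, ppi, gm):
        for a, b, d in net.graph.edges(data=True):
            merged.add_edge(a, b, source=d.get("source", ""))
    disease_genes = {str(g).upper() for g in (disease_genes or ())}
    for n in merged.graph.nodes:
        merged.graph.nodes[n]["disease"] = n in disease_genes
    return merged, intersection


@dataclass
class CentralityRow:
    node_id: str
    aspl: float  # average shortest path length, hops
    betweenness: float  # normalised to [0, 1]


@dataclass
class TargetScore:
    node_id: str
    r: float
    aspl: float
    betweenness: float


def node_centralities(g: LayeredNetwork | nx.Graph) -> list[CentralityRow]:
    """Average shortest path length and betweenness per node.

    Both statistics are computed within each connected component:
    betweenness is normalised by (n-1)(n-2)/2 of the component and ASPL
    averages only over reachable nodes.  Isolated nodes have no defined
    ASPL and are excluded with a warning.
    """
    graph = g.graph if isinstance(g, LayeredNetwork) else g
    if graph.number_of_nodes() < 3:
        raise ValueError("centralities need at least 3 nodes")
    rows: list[CentralityRow] = []
    isolated = [n for n in graph if graph.degree(n) == 0]
    if isolated:
        warnings.warn(f"isolated nodes excluded from centralities: {sorted(isolated)}")
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if sub.number_of_nodes() < 2:
            continue
        bc = nx.betweenness_centrality(sub, normalized=sub.number_of_nodes() > 2)
        spl = dict(nx.all_pairs_shortest_path_length(sub))
        for n in sub:
            others = [d for m, d in spl[n].items() if m != n]
            rows.append(CentralityRow(str(n), float(np.mean(others)), float(bc[n])))
    rows.sort(key=lambda r: r.node_id)
    return rows


def r_score(rows: list[CentralityRow]) -> list[TargetScore]:
    """Equal-weight min-max combination of ASPL and reciprocal betweenness.

    Candidates with zero betweenness are excluded (their reciprocal is
    undefined) with a warning.  If all ASPL values coincide the first term
    is 0 for every candidate; likewise for the betweenness term.
    """
    usable = [r for r in rows if r.betweenness > 0]
    dropped = [r.node_id for r in rows if r.betweenness <= 0]
    if dropped:
        warnings.warn(f"candidates with zero betweenness excluded: {dropped}")
    if len(usable) < 2:
        raise ValueError("need at least 2 candidates with positive betweenness")
    a = np.array([r.aspl for r in usable])
    rb = np.array([1.0 / r.betweenness for r in usable])
    a_span = a.max() - a.min()
    rb_span = rb.max() - rb.min()
    term_a = (a - a.min()) / a_span if a_span > 0 else np.zeros_like(a)
    term_b = (rb - rb.min()) / rb_span if rb_span > 0 else np.zeros_like(rb)
    r = 0.5 * term_a + 0.5 * term_b
    return [
        TargetScore(row.node_id, float(ri), row.aspl, row.betweenness)
        for row, ri in zip(usable, r)
    ]


def rank_targets(scores: list[TargetScore], top_k: int | None = None) -> list[TargetScore]:
    """Ascending R; ties broken by node id so ranking is deterministic."""
    ranked = sorted(scores, key=lambda s: (s.r, s.node_id))
    if top_k is None:
        return ranked
    if top_k > len(ranked):
        warnings.warn(f"top_k={top_k} exceeds {len(ranked)} candidates; returning all")
        return ranked
    return ranked[:top_k]


def read_edge_list(path) -> list[tuple[str, str]]:
    """Read a 2-column TSV or a SIF (``source relation target``) edge file."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                edges.append((parts[0], parts[1]))
            elif len(parts) >= 3:
                edges.append((parts[0], parts[2]))  # SIF: src relation tgt
            else:
                raise ValueError(f"malformed edge line: {line!r}")
    return edges


def write_sif(net: LayeredNetwork, path, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for a, b, d in net.graph.edges(data=True):
            fh.write(f"{a}\t{d.get('source') or relation}\t{b}\n")


def write_graphml(net: LayeredNetwork, path) -> None:
    nx.write_graphml(net.graph, path)
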