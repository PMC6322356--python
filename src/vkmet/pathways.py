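"""Pathway over-representation and topology impact.

Each pathway is a compound set, optionally with the intra-pathway reaction
graph as an undirected edge list.  Enrichment of annotated markers is the
upper-tail hypergeometric probability; the topology "impact" of a hit set
is the fraction of the pathway's relative-betweenness-centrality mass
carried by the matched compounds, so hits at topological bottlenecks score
high even when few.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
from scipy import stats

from .annotate import MatchResult

__all__ = [
    "PathwayDef",
    "PathwayResult",
    "ora_pvalue",
    "pathway_impact",
    "pathway_summary",
    "read_gmt",
    "read_pathway_edges",
]


@dataclass
class PathwayDef:
    pathway_id: str
    name: str
    member_compounds: frozenset
    edges: tuple = ()

    def __post_init__(self) -> None:
        self.member_compounds = frozenset(self.member_compounds)
        for a, b in self.edges:
            if a not in self.member_compounds or b not in self.member_compounds:
                raise ValueError(
                    f"edge ({a},{b}) references non-members of {self.pathway_id}"
                )


@dataclass
class PathwayResult:
    pathway_id: str
    name: str
    n_hits: int
    p_value: float
    p_adjusted: float
    impact: float
    hit_ids: tuple


def ora_pvalue(n_hits: int, pathway_size: int, universe_size: int, n_selected: int) -> float:
    """Hypergeometric over-representation p-value, P(X >= n_hits).

    X counts how many of ``n_selected`` draws (without replacement from a
    universe of ``universe_size`` compounds) fall in a pathway of
    ``pathway_size`` members.
    """
    if not (0 <= n_hits <= min(pathway_size, n_selected)):
        raise ValueError("n_hits inconsistent with pathway_size/n_selected")
    if pathway_size > universe_size or n_selected > universe_size:
        raise ValueError("pathway or selection larger than universe")
    if n_hits == 0:
        return 1.0
    return float(stats.hypergeom.sf(n_hits - 1, universe_size, pathway_size, n_selected))


def pathway_impact(p: PathwayDef, matched) -> float:
    """Share of the pathway's betweenness-centrality mass held by ``matched``.

    Relative betweenness centrality is computed on the pathway graph
    (members as nodes, supplied edges).  When the graph carries no
    betweenness mass at all (edgeless, complete, or too small), centrality
    falls back to uniform 1/|members| per node so the statistic stays
    defined and still reflects hit coverage.
    """
    members = p.member_compounds
    if not members:
        raise ValueError(f"pathway {p.pathway_id} has no members")
    matched = set(matched)
    if not matched <= members:
        raise ValueError("matched compounds must be pathway members")
    g = nx.Graph()
    g.add_nodes_from(members)
    g.add_edges_from(p.edges)
    bc = nx.betweenness_centrality(g, normalized=True)
    total = sum(bc.values())
    if total <= 0:
        bc = {n: 1.0 / len(members) for n in members}
        total = 1.0
    return sum(bc[n] for n in matched) / total


def pathway_summary(
    matches: list[MatchResult],
    db: list[PathwayDef],
    universe_size: int,
    n_selected: int | None = None,
) -> list[PathwayResult]:
    """One result per pathway with at least one hit, sorted by (p, -impact).

    The hit set of a pathway is the distinct annotated KEGG ids among
    ``matches`` that are members.  ``n_selected`` defaults to the number of
    distinct annotated compounds.  Raw p-values drive the ordering; a BH
    column is included for transparency.
    """
    if not db:
        raise ValueError("empty pathway database")
    hits_universe = {m.compound.kegg_id for m in matches if m.annotated and m.compound.kegg_id}
    if n_selected is None:
        n_selected = len(hits_universe)
    results = []
    for p in db:
        hit = sorted(hits_universe & p.member_compounds)
        if not hit:
            continue
        pv = ora_pvalue(len(hit), len(p.member_compounds), universe_size, n_selected)
        imp = pathway_impact(p, hit)
        results.append(PathwayResult(p.pathway_id, p.name, len(hit), pv, 1.0, imp, tuple(hit)))
    if results:
        from .markers import bh_adjust

        adj = bh_adjust([r.p_value for r in results])
        for r, a in zip(results, adj):
            r.p_adjusted = float(a)
    results.sort(key=lambda r: (r.p_value, -r.impact, r.pathway_id))
    return results


def read_gmt(path) -> list[PathwayDef]:
    """Read pathway membership from GMT (id, description, members...)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            out.append(PathwayDef(parts[0], parts[1], frozenset(parts[2:])))
    return out


def read_pathway_edges(path) -> dict[str, list[tuple[str, str]]]:
    """Read per-pathway edges from a TSV ``pathway_id  source  target``."""
    edges: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, a, b = line.split("\t")[:3]
            edges.setdefault(pid, []).append((a, b))
    return edges
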