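"""Synthetic study generator and bundled reference tables.

The feature-table generator emulates the four-group rat design the pipeline
analyses — control, model (tumour-cell injected), and two treated groups
(kansui, vinegar-processed kansui) of six animals each — as a log-normal
intensity model: each feature draws a log-scale baseline mean shared across
groups, a chosen subset of marker features is shifted up or down in the
model group, and treated-group marker means move back toward control by a
``recovery`` fraction.  The interactome generator plants a single
cut-vertex "bridge" protein between two otherwise disconnected communities
holding the compound-target and metabolite-gene seed sets, so network
ranking has a known correct answer.

Three reference tables used throughout the tests ship with the package:
``table1`` (16 identified serum/urine marker metabolites), ``table2``
(31 herbal compounds with oral bioavailability and drug-likeness) and
``table3`` (12 candidate targets with network centralities).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .annotate import CompoundRecord
from .features import FeatureTable
from .netpharm import AdmeCompound, CentralityRow

__all__ = [
    "SimParams",
    "SyntheticStudy",
    "SyntheticInteractome",
    "GROUPS",
    "generate_feature_study",
    "generate_interactome",
    "load_fixture",
    "table1_library",
    "table2_compounds",
    "table3_rows",
]

GROUPS = ("control", "model", "kansui", "vkansui")


@dataclass
class SimParams:
    """Study-generator settings.

    Defaults mirror the study design the pipeline targets: 6 animals per
    group, a few hundred aligned features, a planted-marker log-fold-change
    of 1.1 natural-log units against a log-scale noise SD of 0.4 (a strong
    but not degenerate metabolic perturbation), and treated groups that
    reverse 80% of the model shift.
    """

    n_per_group: int = 6
    n_features: int = 300
    n_markers: int = 20
    log_fold_change: float = 1.1
    recovery: float = 0.8
    noise_sd: float = 0.4
    seed: int = 0
    n_qc: int = 0
    base_log_mean: float = 10.0
    base_log_spread: float = 0.3

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not (0 <= self.n_markers <= self.n_features):
            raise ValueError("need 0 <= n_markers <= n_features")
        if not (0.0 <= self.recovery <= 1.0):
            raise ValueError("recovery must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SyntheticStudy:
    table: FeatureTable
    truth_markers: set
    truth_directions: dict  # feature id -> +1 (up in model) / -1 (down)


@dataclass
class SyntheticInteractome:
    edges: list
    planted_bridge: str
    seed_compound_targets: set
    seed_metabolite_genes: set
    nodes: list = field(default_factory=list)


def generate_feature_study(params: SimParams) -> SyntheticStudy:
    """Simulate a four-group feature table with planted differential markers.

    Intensities are exp(Normal) per feature and sample.  Marker features
    are shifted by ±``log_fold_change`` in the model group; treated-group
    marker means sit at ``model + recovery * (control - model)`` on the log
    scale, i.e. full recovery returns them to the control mean.  Identical
    parameters (including the seed) give identical tables.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    nf, npg = params.n_features, params.n_per_group
    feature_ids = [f"F{i + 1:04d}" for i in range(nf)]
    mz = rng.uniform(100.0, 1000.0, nf)
    rt = rng.uniform(0.2, 15.0, nf)
    base_mu = rng.normal(params.base_log_mean, params.base_log_spread, nf)

    marker_idx = rng.choice(nf, size=params.n_markers, replace=False)
    directions = rng.choice([-1.0, 1.0], size=params.n_markers)
    shift = np.zeros(nf)
    shift[marker_idx] = directions * params.log_fold_change

    # per-group log-mean matrix (features x groups)
    mu = {
        "control": base_mu,
        "model": base_mu + shift,
        "kansui": base_mu + (1.0 - params.recovery) * shift,
        "vkansui": base_mu + (1.0 - params.recovery) * shift,
    }
    cols, sample_ids, groups, is_qc = [], [], [], []
    for g in GROUPS:
        noise = rng.normal(0.0, params.noise_sd, (nf, npg))
        cols.append(np.exp(mu[g][:, None] + noise))
        sample_ids += [f"{g}_{k + 1}" for k in range(npg)]
        groups += [g] * npg
        is_qc += [False] * npg
    if params.n_qc:
        # QC = pooled mean profile with small technical noise
        qc_mu = np.mean([mu[g] for g in GROUPS], axis=0)
        noise = rng.normal(0.0, params.noise_sd / 4.0, (nf, params.n_qc))
        cols.append(np.exp(qc_mu[:, None] + noise))
        sample_ids += [f"QC_{k + 1}" for k in range(params.n_qc)]
        groups += ["qc"] * params.n_qc
        is_qc += [True] * params.n_qc

    table = FeatureTable(
        feature_ids, mz, rt, np.hstack(cols), sample_ids, groups, np.array(is_qc)
    )
    truth = {feature_ids[i] for i in marker_idx}
    truth_dir = {feature_ids[i]: int(d) for i, d in zip(marker_idx, directions)}
    return SyntheticStudy(table, truth, truth_dir)


def generate_interactome(
    n_proteins: int, mean_degree: float = 4.0, seed: int = 0, n_seeds_per_side: int = 3
) -> SyntheticInteractome:
    """Random two-community interactome joined by one planted bridge protein.

    Each community is a connected random graph (random spanning tree plus
    extra edges up to the requested mean degree).  The only path between
    communities runs through the bridge node, making it a cut vertex with
    the dominant betweenness.  Compound-target seeds live in one community
    and metabolite-gene seeds in the other.
    """
    if n_proteins < 10:
        raise ValueError("n_proteins must be >= 10")
    if mean_degree < 2:
        raise ValueError("mean_degree must be >= 2")
    rng = np.random.default_rng(seed)
    bridge = "BRD1"
    half = (n_proteins - 1) // 2
    side_a = [f"PA{i + 1:03d}" for i in range(half)]
    side_b = [f"PB{i + 1:03d}" for i in range(n_proteins - 1 - half)]

    def community(nodes: list) -> set:
        edges = set()
        order = list(rng.permutation(nodes))
        for u, v in zip(order, order[1:]):  # spanning tree keeps it connected
            edges.add(tuple(sorted((u, v))))
        target_edges = int(mean_degree * len(nodes) / 2)
        tries = 0
        while len(edges) < target_edges and tries < 50 * target_edges:
            u, v = rng.choice(nodes, 2, replace=False)
            if u != v:
                edges.add(tuple(sorted((u, v))))
            tries += 1
        return edges

    edges = community(side_a) | community(side_b)
    k = max(1, min(3, len(side_a), len(side_b)))
    for u in rng.choice(side_a, k, replace=False):
        edges.add(tuple(sorted((bridge, u))))
    for v in rng.choice(side_b, k, replace=False):
        edges.add(tuple(sorted((bridge, v))))
    n_seed = min(n_seeds_per_side, len(side_a), len(side_b))
    seeds_a = set(rng.choice(side_a, n_seed, replace=False).tolist())
    seeds_b = set(rng.choice(side_b, n_seed, replace=False).tolist())
    return SyntheticInteractome(
        edges=sorted(edges),
        planted_bridge=bridge,
        seed_compound_targets=seeds_a,
        seed_metabolite_genes=seeds_b,
        nodes=[bridge] + side_a + side_b,
    )


_FIXTURES = {
    "table1": "table1_metabolites.tsv",
    "table2": "table2_adme.tsv",
    "table3": "table3_centralities.tsv",
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a bundled reference table (``table1`` | ``table2`` | ``table3``)."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}")
    ref = resources.files("vkmet.data") / _FIXTURES[name]
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def table1_library() -> list[CompoundRecord]:
    """The 16 identified marker metabolites as an annotation library."""
    df = load_fixture("table1")
    return [
        CompoundRecord(
            name=r.metabolite,
            formula=r.formula,
            adducts=(r.adduct,),
            kegg_id=r.kegg_id,
            pathway_names=tuple(s.strip() for s in str(r.pathways).split(";")),
        )
        for r in df.itertuples()
    ]


def table2_compounds() -> list[AdmeCompound]:
    """The 31 herbal compounds with OB/DL scores."""
    df = load_fixture("table2")
    return [
        AdmeCompound(r.compound_id, r.name, float(r.ob), float(r.dl))
        for r in df.itertuples()
    ]


def table3_rows() -> list[CentralityRow]:
    """The 12 candidate targets with printed centralities."""
    df = load_fixture("table3")
    return [
        CentralityRow(r.node, float(r.aspl), float(r.betweenness))
        for r in df.itertuples()
    ]
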