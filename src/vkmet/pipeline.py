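"""End-to-end orchestration of the analysis from a single config.

The pipeline chains preprocess -> chemometrics -> marker screen ->
annotation -> pathway analysis -> network assembly -> target ranking over
file-based inputs, writes every artifact into an output directory and
records a manifest (inputs, thresholds, seed, SHA-256 checksums) so a rerun
with the same config is verifiably identical.  A demo-input writer builds a
complete, internally consistent input bundle from the synthetic-data
generator so the whole chain can run without any external resource.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import chemometrics as chem
from . import features as feat
from . import markers as mk
from . import netpharm as np_mod
from . import pathways as pw
from . import simdata

__all__ = ["PipelineConfig", "run_pipeline", "write_demo_inputs"]

STAGES = ("preprocess", "chemometrics", "screen", "annotate", "pathways", "network", "rank")


@dataclass
class PipelineConfig:
    feature_table: str
    metadata: str
    library: str
    pathway_gmt: str
    pathway_edges: str | None
    ct_table: str
    ppi_table: str
    gm_table: str
    adme_table: str
    output_dir: str
    disease_genes: str | None = None
    whitelist: tuple = ()
    vip_min: float = 1.5
    alpha: float = 0.05
    tol_ppm: float = 10.0
    ob_min: float = 30.0
    dl_min: float = 0.18
    top_k: int = 6
    n_perm: int = 200
    cv_folds: int = 7
    seed: int = 0
    impute_rule: str = "half_min"
    qc_max_rsd: float = 30.0
    control_group: str = "control"
    model_group: str = "model"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "whitelist" in raw and raw["whitelist"] is not None:
            raw["whitelist"] = tuple(raw["whitelist"])
        return cls(**raw)

    def validate(self) -> None:
        for attr in ("vip_min", "alpha", "tol_ppm", "top_k", "n_perm", "cv_folds"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        for attr in ("feature_table", "metadata", "library", "pathway_gmt",
                     "ct_table", "ppi_table", "gm_table", "adme_table"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr}: no such file {p!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from the single top-level seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save_df(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        artifacts[name] = str(p)

    # -- preprocess ---------------------------------------------------------
    table = feat.read_feature_table(config.feature_table, config.metadata)
    table = feat.impute_missing(table, config.impute_rule)
    table = feat.qc_rsd_filter(table, config.qc_max_rsd)
    cm_mask = table.sample_mask(config.control_group) | table.sample_mask(config.model_group)
    sub = feat.FeatureTable(
        table.feature_ids, table.mz, table.rt,
        table.intensities[:, cm_mask],
        [s for s, m in zip(table.sample_ids, cm_mask) if m],
        [g for g, m in zip(table.groups, cm_mask) if m],
        table.is_qc[cm_mask],
    )
    scaled = feat.pareto_scale(sub)
    feat.write_feature_table(table, out / "preprocessed.csv", out / "preprocessed_meta.tsv")
    artifacts["preprocessed.csv"] = str(out / "preprocessed.csv")
    artifacts["preprocessed_meta.tsv"] = str(out / "preprocessed_meta.tsv")

    # -- chemometrics -------------------------------------------------------
    y = sub.groups
    model = chem.fit_oplsda(scaled, y, n_orth="auto", cv_folds=config.cv_folds,
                            seed=_stage_seed(config.seed, "oplsda"))
    perm = chem.permutation_test(scaled, y, n_perm=config.n_perm,
                                 seed=_stage_seed(config.seed, "perm"),
                                 n_orth=model.n_orth, cv_folds=config.cv_folds)
    vips = chem.vip_scores(model)
    p_cov, p_corr, _ = chem.s_plot(model, scaled)
    save_df(pd.DataFrame({"feature_id": scaled.feature_ids, "vip": vips,
                          "p_cov": p_cov, "p_corr": p_corr}), "chemometrics_features.tsv")
    summary = {
        "r2x": model.r2x, "r2y": model.r2y, "q2": model.q2, "n_orth": model.n_orth,
        "permutation_p_q2": perm.p_q2, "n_perm": config.n_perm,
    }
    (out / "model_summary.json").write_text(json.dumps(summary, indent=2))
    artifacts["model_summary.json"] = str(out / "model_summary.json")

    # -- screen -------------------------------------------------------------
    marker_recs = mk.screen_markers(table, vips, config.vip_min, config.alpha,
                                    config.control_group, config.model_group)
    treated = sorted({g for g in table.groups
                      if g not in (config.control_group, config.model_group, "qc")})
    if treated:
        mk.recovery_assessment(table, marker_recs, tuple(treated), config.model_group)
    save_df(pd.DataFrame([{
        "feature_id": r.feature_id, "vip": r.vip, "p_value": r.p_value,
        "p_adjusted": r.p_adjusted, "fold_change": r.fold_change, "trend": r.trend,
        **{f"recovery_{g}": r.recovery_flags.get(g, "") for g in treated},
    } for r in marker_recs]), "markers.tsv")

    # -- annotate -----------------------------------------------------------
    library = ann.read_library(config.library)
    fid_to_idx = {f: i for i, f in enumerate(table.feature_ids)}
    queries = []
    for r in marker_recs:
        i = fid_to_idx[r.feature_id]
        for mode in ("pos", "neg"):
            queries.append((r.feature_id, table.mz[i], mode))
    matches = [m for m in ann.match_library(queries, library, config.tol_ppm) if m.annotated]
    best: dict[str, ann.MatchResult] = {}
    for m in matches:
        if m.feature_id not in best or abs(m.ppm_error) < abs(best[m.feature_id].ppm_error):
            best[m.feature_id] = m
    matches = [best[f] for f in sorted(best)]
    save_df(pd.DataFrame([{
        "feature_id": m.feature_id, "compound": m.compound.name,
        "kegg_id": m.compound.kegg_id, "adduct": m.adduct,
        "theoretical_mz": m.theoretical_mz, "ppm_error": m.ppm_error,
    } for m in matches]), "annotations.tsv")

    # -- pathways -----------------------------------------------------------
    db = pw.read_gmt(config.pathway_gmt)
    if config.pathway_edges:
        edge_map = pw.read_pathway_edges(config.pathway_edges)
        db = [pw.PathwayDef(p.pathway_id, p.name, p.member_compounds,
                            tuple(edge_map.get(p.pathway_id, ()))) for p in db]
    universe = len({c.kegg_id for c in library if c.kegg_id})
    pw_results = pw.pathway_summary(matches, db, universe_size=max(universe, 1))
    save_df(pd.DataFrame([{
        "pathway_id": r.pathway_id, "name": r.name, "n_hits": r.n_hits,
        "p_value": r.p_value, "p_adjusted": r.p_adjusted, "impact": r.impact,
    } for r in pw_results]), "pathways.tsv")

    # -- network ------------------------------------------------------------
    adme = np_mod.read_adme_table(config.adme_table)
    selected, adme_report = np_mod.adme_filter(adme, config.ob_min, config.dl_min,
                                               set(config.whitelist))
    ct = np_mod.compound_target_network(selected, np_mod.read_edge_list(config.ct_table))
    gm_pairs = np_mod.read_edge_list(config.gm_table)
    met_ids = sorted({m.compound.kegg_id for m in matches if m.compound.kegg_id})
    gm = np_mod.gene_metabolite_network(met_ids, gm_pairs)
    seeds = ct.nodes_in_layer("target") | gm.nodes_in_layer("pathway_gene")
    ppi = np_mod.expand_ppi(seeds, np_mod.read_edge_list(config.ppi_table))
    disease = set()
    if config.disease_genes:
        disease = {line.strip() for line in open(config.disease_genes) if line.strip()}
    merged, intersection = np_mod.merge_tripartite(ct, ppi, gm, disease)
    np_mod.write_sif(merged, out / "network.sif")
    np_mod.write_graphml(merged, out / "network.graphml")
    artifacts["network.sif"] = str(out / "network.sif")
    artifacts["network.graphml"] = str(out / "network.graphml")
    (out / "adme_report.json").write_text(json.dumps(adme_report, indent=2))
    artifacts["adme_report.json"] = str(out / "adme_report.json")

    # -- rank ---------------------------------------------------------------
    rows = np_mod.node_centralities(merged)
    cand = [r for r in rows if r.node_id in intersection]
    ranked: list[np_mod.TargetScore] = []
    if len([r for r in cand if r.betweenness > 0]) >= 2:
        ranked = np_mod.rank_targets(np_mod.r_score(cand), config.top_k)
    save_df(pd.DataFrame([{
        "node": s.node_id, "aspl": s.aspl, "betweenness": s.betweenness,
        "r": s.r, "rank": i + 1,
    } for i, s in enumerate(ranked)]), "ranked_targets.tsv")

    manifest = {
        "stages": list(STAGES),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "seed": config.seed,
        "n_markers": len(marker_recs),
        "n_annotated": len(matches),
        "n_pathways": len(pw_results),
        "n_candidates": len(cand),
        "intersection": sorted(intersection),
        "artifacts": {n: _sha256(Path(p)) for n, p in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def write_demo_inputs(directory, seed: int = 0, params: simdata.SimParams | None = None) -> PipelineConfig:
    """Write a complete synthetic input bundle and return its config.

    The feature study plants 16 markers whose m/z are set to the theoretical
    adduct m/z of the bundled 16-metabolite library (small random ppm
    offsets), so the annotation stage has true positives to find; pathway
    membership and edges are derived from the library's own pathway names;
    the network layers come from a planted-bridge interactome whose
    compound-target seeds are wired to the ADME-selected compounds.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if params is None:
        params = simdata.SimParams(n_markers=16, seed=seed)
    study = simdata.generate_feature_study(params)
    library = simdata.table1_library()

    table = study.table
    truth = sorted(study.truth_markers)
    for fid, comp in zip(truth, library):
        i = table.feature_ids.index(fid)
        theo = ann.adduct_mz(ann.monoisotopic_mass(comp.formula), comp.adducts[0])
        table.mz[i] = theo * (1.0 + rng.uniform(-5e-6, 5e-6))  # within +-5 ppm
    feat.write_feature_table(table, directory / "features.csv", directory / "metadata.tsv")

    lib_rows = []
    for comp in library:
        lib_rows.append({
            "name": comp.name, "formula": comp.formula,
            "adducts": ",".join(comp.adducts), "kegg_id": comp.kegg_id,
            "pathways": "; ".join(comp.pathway_names),
        })
    pd.DataFrame(lib_rows).to_csv(directory / "library.tsv", sep="\t", index=False)

    pathways: dict[str, list[str]] = {}
    for comp in library:
        for pname in comp.pathway_names:
            pathways.setdefault(pname, [])
            if comp.kegg_id not in pathways[pname]:
                pathways[pname].append(comp.kegg_id)
    with open(directory / "pathways.gmt", "w") as fh:
        for k, (pname, members) in enumerate(sorted(pathways.items())):
            fh.write("\t".join([f"PW{k + 1:02d}", pname] + members) + "\n")
    with open(directory / "pathway_edges.tsv", "w") as fh:
        for k, (pname, members) in enumerate(sorted(pathways.items())):
            for a, b in zip(members, members[1:]):  # chain within pathway
                fh.write(f"PW{k + 1:02d}\t{a}\t{b}\n")

    inter = simdata.generate_interactome(60, mean_degree=4.0, seed=seed)
    with open(directory / "ppi.tsv", "w") as fh:
        for a, b in inter.edges:
            fh.write(f"{a}\t{b}\n")
    adme = simdata.table2_compounds()
    pd.DataFrame([{"compound_id": c.compound_id, "name": c.name,
                   "ob": c.ob, "dl": c.dl} for c in adme]).to_csv(
        directory / "adme.tsv", sep="\t", index=False)
    selected, _ = np_mod.adme_filter(adme)
    targets = sorted(inter.seed_compound_targets)
    with open(directory / "ct.tsv", "w") as fh:
        for k, cid in enumerate(sorted(selected)):
            fh.write(f"{cid}\t{targets[k % len(targets)]}\n")
    genes = sorted(inter.seed_metabolite_genes)
    kegg_ids = sorted({c.kegg_id for c in library})
    with open(directory / "gm.tsv", "w") as fh:
        for k, kid in enumerate(kegg_ids):
            fh.write(f"{kid}\t{genes[k % len(genes)]}\n")

    return PipelineConfig(
        feature_table=str(directory / "features.csv"),
        metadata=str(directory / "metadata.tsv"),
        library=str(directory / "library.tsv"),
        pathway_gmt=str(directory / "pathways.gmt"),
        pathway_edges=str(directory / "pathway_edges.tsv"),
        ct_table=str(directory / "ct.tsv"),
        ppi_table=str(directory / "ppi.tsv"),
        gm_table=str(directory / "gm.tsv"),
        adme_table=str(directory / "adme.tsv"),
        output_dir=str(directory / "out"),
        seed=seed,
        n_perm=20,
    )
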