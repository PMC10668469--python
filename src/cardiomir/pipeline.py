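"""Stage orchestration: simulate -> DE -> cluster -> network -> protein ->
reporter, with every stage's table written to a workspace directory and, for
synthetic runs, a ground-truth recovery report.

A run is described by a YAML file with up to four sections::

    simulate: true            # or false to read real inputs
    pipeline:  {...}          # PipelineConfig fields (thresholds, bins, seed)
    simulation: {...}         # SimulationConfig fields (synthetic runs)
    inputs:    {...}          # paths (non-synthetic runs)

Reruns with the same spec and seed are byte-identical: all randomness flows
from one integer-seeded generator and tables are written with a fixed float
format.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import clustering, de, network
from . import io as cio
from . import reporter as rep
from .config import PipelineConfig
from .datatypes import CountMatrix, GeneSetCollection, SampleTable, TargetMap
from .simulate import SimulationConfig, SyntheticStudy, simulate_study

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

REQUIRED_INPUTS = ("smallrna_counts", "mrna_counts", "samples", "target_map")
OPTIONAL_INPUTS = ("protein_group_a", "protein_group_b", "gene_sets",
                   "protein_gene_map")


@dataclass
class RunSpec:
    simulate: bool
    pipeline: PipelineConfig
    simulation: SimulationConfig | None
    inputs: dict[str, str]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        simulate = bool(raw.get("simulate", True))
        pcfg = PipelineConfig(**(raw.get("pipeline") or {}))
        scfg = SimulationConfig(**(raw.get("simulation") or {})) if simulate else None
        inputs = dict(raw.get("inputs") or {})
        if not simulate:
            missing = [k for k in REQUIRED_INPUTS if k not in inputs]
            if missing:
                raise ValueError(f"non-synthetic run is missing required "
                                 f"input path(s): {missing}")
        return cls(simulate, pcfg, scfg, inputs)


@dataclass
class StudyBundle:
    """The pipeline's input bundle, from simulation or from files."""
    smallrna: CountMatrix
    mrna: CountMatrix
    samples: SampleTable
    target_map: TargetMap
    protein_groups: dict[str, pd.DataFrame] | None
    protein_group_labels: pd.Series | None
    gene_sets: GeneSetCollection | None
    protein_gene_map: dict[str, str] | None
    truth: object | None = None
    shared_samples: list[str] | None = None


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", float_format=FLOAT_FMT, **kw)


# ---------------------------------------------------------------------------
# input acquisition
# ---------------------------------------------------------------------------

def stage_simulate(sim_cfg: SimulationConfig, outdir: Path) -> StudyBundle:
    study = simulate_study(sim_cfg)
    d = outdir / "inputs"
    d.mkdir(parents=True, exist_ok=True)
    cio.write_count_matrix(study.smallrna, d / "smallrna_counts.tsv")
    cio.write_count_matrix(study.mrna, d / "mrna_counts.tsv")
    cio.write_sample_table(study.samples, d / "samples.tsv")
    cio.write_target_map(study.target_map, d / "target_map.tsv")
    for name, table in study.protein_groups.items():
        cio.write_protein_table(table, d / f"protein_{name}.tsv")
    cio.write_gmt(study.gene_sets, d / "gene_sets.gmt")
    study.truth.write(d)
    gene_map = {p: p.removeprefix("prot_")
                for p in study.truth.proteins["protein_id"]}
    _write(pd.Series(gene_map, name="mrna_id").rename_axis("protein_id")
           .to_frame(), d / "protein_gene_map.tsv")
    return StudyBundle(
        smallrna=study.smallrna, mrna=study.mrna, samples=study.samples,
        target_map=study.target_map, protein_groups=study.protein_groups,
        protein_group_labels=study.protein_group_labels,
        gene_sets=study.gene_sets, protein_gene_map=gene_map,
        truth=study.truth, shared_samples=study.shared_samples)


def load_inputs(paths: dict[str, str]) -> StudyBundle:
    smallrna = cio.read_count_matrix(paths["smallrna_counts"])
    mrna = cio.read_count_matrix(paths["mrna_counts"])
    samples = cio.read_sample_table(paths["samples"])
    tm = cio.read_target_map(paths["target_map"])
    protein_groups = None
    labels = None
    if "protein_group_a" in paths and "protein_group_b" in paths:
        a = cio.read_protein_table(paths["protein_group_a"])
        b = cio.read_protein_table(paths["protein_group_b"])
        protein_groups = {"group_a": a, "group_b": b}
        labels = pd.Series({**{s: "group_a" for s in a.columns},
                            **{s: "group_b" for s in b.columns}})
    gsc = cio.read_gmt(paths["gene_sets"]) if "gene_sets" in paths else None
    gene_map = None
    if "protein_gene_map" in paths:
        m = pd.read_csv(paths["protein_gene_map"], sep="\t", index_col=0)
        gene_map = m.iloc[:, 0].to_dict()
    shared = sorted(set(smallrna.sample_ids) & set(mrna.sample_ids))
    return StudyBundle(smallrna, mrna, samples, tm, protein_groups, labels,
                       gsc, gene_map, truth=None, shared_samples=shared)


# ---------------------------------------------------------------------------
# analysis stages
# ---------------------------------------------------------------------------

def stage_de(bundle: StudyBundle, cfg: PipelineConfig, outdir: Path) -> dict:
    d = outdir / "de"
    d.mkdir(parents=True, exist_ok=True)
    small = cio.filter_unique_features(bundle.smallrna)
    sf_s = de.estimate_size_factors(small)
    sf_m = de.estimate_size_factors(bundle.mrna)
    norm_s = de.normalize_counts(small, sf_s, log2=True)
    norm_m = de.normalize_counts(bundle.mrna, sf_m, log2=True)
    de_small = de.fit_nb_continuous(small, bundle.samples)
    de_mrna = de.fit_nb_continuous(bundle.mrna, bundle.samples)
    coords, varfrac = de.pca_samples(norm_s)
    comp = de.subtype_composition(small)

    _write(pd.DataFrame({"size_factor": sf_s}), d / "size_factors_smallrna.tsv",
           index_label="sample_id")
    _write(pd.DataFrame({"size_factor": sf_m}), d / "size_factors_mrna.tsv",
           index_label="sample_id")
    _write(de_small, d / "de_smallrna.tsv", index_label="feature_id")
    _write(de_mrna, d / "de_mrna.tsv", index_label="feature_id")
    _write(coords, d / "pca_smallrna.tsv", index_label="sample_id")
    _write(pd.DataFrame({"variance_fraction": varfrac},
                        index=[f"PC{i+1}" for i in range(len(varfrac))]),
           d / "pca_variance_smallrna.tsv", index_label="component")
    _write(comp, d / "subtype_composition.tsv", index_label="subtype")
    return {"small": small, "de_small": de_small, "de_mrna": de_mrna,
            "norm_small": norm_s, "norm_mrna": norm_m,
            "pca_varfrac": varfrac}


def stage_cluster(state: dict, bundle: StudyBundle, cfg: PipelineConfig,
                  outdir: Path) -> dict:
    d = outdir / "cluster"
    d.mkdir(parents=True, exist_ok=True)
    de_small = state["de_small"]
    sig = de_small.index[(de_small["padj"].astype(float) < cfg.alpha_de)
                         & de_small["padj"].notna()]
    mirnas = [f for f in sig
              if state["small"].annotations.at[f, "subtype"] == "miRNA"]
    profiles, const = clustering.bin_mean_zscores(
        state["norm_small"].loc[mirnas], bundle.samples, cfg.age_bin_edges)
    ca = clustering.cluster_zprofiles(profiles, cfg.min_cluster_size,
                                      cfg.cluster_cut_height)
    _write(profiles, d / "zprofiles.tsv", index_label="feature_id")
    _write(pd.DataFrame({"cluster": ca.labels}), d / "clusters.tsv",
           index_label="feature_id")
    _write(ca.mean_profiles, d / "cluster_mean_profiles.tsv",
           index_label="cluster")
    return {"clusters": ca, "profiles": profiles,
            "constant_features": const, "de_mirnas": mirnas}


def stage_network(state: dict, bundle: StudyBundle, cfg: PipelineConfig,
                  outdir: Path) -> dict:
    d = outdir / "network"
    d.mkdir(parents=True, exist_ok=True)
    de_small, de_mrna = state["de_small"], state["de_mrna"]
    sig_small = de_small.index[(de_small["padj"].astype(float) < cfg.alpha_de)
                               & de_small["padj"].notna()]
    de_mirnas = [f for f in sig_small
                 if state["small"].annotations.at[f, "subtype"] == "miRNA"]
    sig_mrna = list(de_mrna.index[(de_mrna["padj"].astype(float) < cfg.alpha_de)
                                  & de_mrna["padj"].notna()])
    pairs = network.candidate_pairs(de_mirnas, sig_mrna, bundle.target_map)
    edges = network.correlate_pairs(pairs, state["norm_small"],
                                    state["norm_mrna"],
                                    bundle.shared_samples)
    kept = network.filter_anticorrelated(edges, cfg.alpha_corr, cfg.r_max)
    up_t, down_t = network.partition_by_mrna_direction(kept, de_mrna)
    top_down = network.select_top_fraction(down_t, cfg.top_fraction)
    _write(edges, d / "edges_all.tsv", index=False)
    _write(kept, d / "edges_anticorrelated.tsv", index=False)
    _write(up_t, d / "edges_up_targets.tsv", index=False)
    _write(down_t, d / "edges_down_targets.tsv", index=False)
    _write(top_down, d / "edges_top_fraction_down.tsv", index=False)
    for cut in cfg.figure_r_cuts:
        sub = network.threshold_edges(kept, cut)
        _write(sub, d / f"edges_r_below_{cut:g}.tsv", index=False)
    return {"edges": edges, "edges_kept": kept, "edges_up": up_t,
            "edges_down": down_t, "edges_top_down": top_down,
            "de_mirnas": de_mirnas, "sig_mrna": sig_mrna}


def stage_protein(state: dict, bundle: StudyBundle, cfg: PipelineConfig,
                  outdir: Path) -> dict:
    if bundle.protein_groups is None:
        return {}
    d = outdir / "protein"
    d.mkdir(parents=True, exist_ok=True)
    common = network.common_protein_filter(*bundle.protein_groups.values())
    pde = de.fit_two_group(common, bundle.protein_group_labels)
    conc = network.concordant_pairs(pde, state["de_mrna"], cfg.alpha_protein,
                                    id_map=bundle.protein_gene_map)
    cio.write_protein_table(common, d / "common_proteins.tsv")
    _write(pde, d / "protein_de.tsv", index_label="protein_id")
    _write(conc, d / "concordant_proteins.tsv", index=False)
    nets = {}
    for polarity, tag in (("down-miR:up-mRNA:enriched", "enriched"),
                          ("up-miR:down-mRNA:depleted", "depleted")):
        nodes, edges = network.build_tripartite(
            state["edges_kept"], conc, state["de_small"], polarity)
        cio.write_network(nodes, edges, d / f"tripartite_{tag}", format="tsv")
        cio.write_network(nodes, edges, d / f"tripartite_{tag}",
                          format="graphml")
        nets[tag] = (nodes, edges)
    return {"protein_common": common, "protein_de": pde, "concordant": conc,
            "tripartite": nets}


def stage_reporter(state: dict, bundle: StudyBundle, cfg: PipelineConfig,
                   outdir: Path, controls: str = "random") -> dict:
    if bundle.gene_sets is None:
        return {}
    d = outdir / "reporter"
    d.mkdir(parents=True, exist_ok=True)
    de_mrna = state["de_mrna"]
    target_genes = {g for _, g in bundle.target_map.edges}
    # gene-level input: adjusted p of DE mRNAs that are predicted targets
    sig = de_mrna.index[(de_mrna["padj"].astype(float) < cfg.alpha_de)
                        & de_mrna["padj"].notna()]
    de_targets = [g for g in sig if g in target_genes]
    stats = rep.make_gene_stats(de_mrna, genes=de_targets)
    r = cfg.reporter
    res = rep.run_reporter(stats, bundle.gene_sets, r.min_k, r.max_k,
                           r.n_perm, r.alpha, r.figure_alpha, seed=cfg.seed)
    _write(res, d / "reporter_metabolites.tsv")
    out = {"reporter": res, "reporter_stats_genes": list(stats.index)}
    if controls in ("random", "all"):
        n = len(stats)
        chosen, ctrl = rep.random_control_run(
            de_mrna, n=n, gsc=bundle.gene_sets, alpha_de=cfg.alpha_de,
            seed=cfg.seed, min_k=r.min_k, max_k=r.max_k, n_perm=r.n_perm,
            alpha=r.alpha, figure_alpha=r.figure_alpha)
        _write(ctrl, d / "reporter_control_random.tsv")
        out["reporter_control"] = ctrl
    if controls in ("random-nontarget", "all"):
        n = min(len(stats), max(1, int((de_mrna["padj"].astype(float)
                                        < cfg.alpha_de).sum()
                                       - len(target_genes))))
        chosen, ctrl = rep.random_control_run(
            de_mrna, n=n, gsc=bundle.gene_sets, exclude=target_genes,
            alpha_de=cfg.alpha_de, seed=cfg.seed, min_k=r.min_k,
            max_k=r.max_k, n_perm=r.n_perm, alpha=r.alpha,
            figure_alpha=r.figure_alpha)
        _write(ctrl, d / "reporter_control_nontarget.tsv")
        out["reporter_control_nontarget"] = ctrl
    return out


# ---------------------------------------------------------------------------
# ground-truth recovery (synthetic runs)
# ---------------------------------------------------------------------------

def _precision_recall(found: set, truth: set) -> tuple[float, float]:
    tp = len(found & truth)
    prec = tp / len(found) if found else float("nan")
    rec = tp / len(truth) if truth else float("nan")
    return prec, rec


def recovery_report(state: dict, bundle: StudyBundle) -> dict:
    truth = bundle.truth
    feats = truth.features
    de_small, de_mrna = state["de_small"], state["de_mrna"]

    report: dict[str, float] = {}
    for layer, table in (("smallrna", de_small), ("mrna", de_mrna)):
        tf = feats[feats["layer"] == ("smallRNA" if layer == "smallrna" else "mRNA")]
        called = set(table.index[(table["padj"].astype(float) < 0.05)
                                 & table["padj"].notna()])
        true_de = set(tf.index[tf["is_de"]])
        prec, rec = _precision_recall(called & set(tf.index), true_de)
        report[f"de_{layer}_precision"] = prec
        report[f"de_{layer}_recall"] = rec

    ca = state.get("clusters")
    if ca is not None:
        members = feats.index[feats["template_id"].notna()]
        scored = [f for f in members if f in ca.labels.index]
        if scored:
            report["cluster_ari"] = float(adjusted_rand_score(
                feats.loc[scored, "template_id"].astype(int),
                ca.labels.loc[scored]))
            report["cluster_n_scored"] = len(scored)

    kept = state.get("edges_kept")
    if kept is not None:
        found = set(zip(kept["mirna_id"], kept["mrna_id"]))
        e = truth.edges
        planted = set(zip(e[e["kind"] == "planted"]["mirna_id"],
                          e[e["kind"] == "planted"]["mrna_id"]))
        decoy = set(zip(e[e["kind"] == "decoy"]["mirna_id"],
                        e[e["kind"] == "decoy"]["mrna_id"]))
        prec, rec = _precision_recall(found, planted)
        report["edge_precision"] = prec
        report["edge_recall"] = rec
        report["decoy_pass_rate"] = (len(found & decoy) / len(decoy)
                                     if decoy else float("nan"))

    conc = state.get("concordant")
    if conc is not None and bundle.truth is not None:
        found_prot = set(conc["protein_id"])
        true_conc = set(truth.proteins[truth.proteins["concordant"]]["protein_id"])
        prec, rec = _precision_recall(found_prot, true_conc)
        report["concordant_precision"] = prec
        report["concordant_recall"] = rec

    nets = state.get("tripartite")
    if nets:
        found_paths = set()
        for nodes, edges in nets.values():
            enc = edges[edges["kind"] == "encodes"]
            for _, e in edges[edges["kind"] == "targets"].iterrows():
                for _, e2 in enc[enc["source"] == e["target"]].iterrows():
                    found_paths.add((e["source"], e["target"], e2["target"]))
        pt = truth.proteins
        true_paths = set()
        ed = truth.edges
        for _, e in ed[ed["kind"] == "planted"].iterrows():
            hits = pt[(pt["mrna_id"] == e["mrna_id"]) & pt["concordant"]]
            for _, p in hits.iterrows():
                true_paths.add((e["mirna_id"], e["mrna_id"], p["protein_id"]))
        prec, rec = _precision_recall(found_paths, true_paths)
        report["tripartite_precision"] = prec
        report["tripartite_recall"] = rec

    res = state.get("reporter")
    if res is not None:
        gt = truth.gene_sets.set_index("set_id")
        ev = res[res["status"] == "evaluated"].join(gt)
        directional = ev[ev["direction"].isin(["up", "down"])]
        nulls = ev[ev["direction"] == "null"]
        if len(directional):
            report["reporter_direction_accuracy"] = float(
                (directional["call"] == directional["direction"]).mean())
        if len(nulls):
            report["reporter_null_fp_rate"] = float(
                (nulls["call"] != "none").mean())
    return report


# ---------------------------------------------------------------------------
# top-level driver
# ---------------------------------------------------------------------------

def run_pipeline(spec: RunSpec, outdir: str | Path,
                 controls: str = "random") -> dict:
    """Execute every stage, writing all tables beneath ``outdir``.

    Returns the recovery report (synthetic runs) or a stage summary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if spec.simulate:
        bundle = stage_simulate(spec.simulation, outdir)
    else:
        bundle = load_inputs(spec.inputs)
    if len(bundle.shared_samples) < 3:
        raise ValueError("fewer than 3 samples shared between the small-RNA "
                         "and mRNA cohorts")
    cfg = spec.pipeline
    state = stage_de(bundle, cfg, outdir)
    state.update(stage_cluster(state, bundle, cfg, outdir))
    state.update(stage_network(state, bundle, cfg, outdir))
    state.update(stage_protein(state, bundle, cfg, outdir))
    state.update(stage_reporter(state, bundle, cfg, outdir, controls))

    log = {
        "pipeline_config": cfg.to_dict(),
        "simulate": spec.simulate,
        "simulation_config": (spec.simulation.__dict__ if spec.simulation
                              else None),
        "versions": _versions(),
    }
    summary: dict = {
        "n_de_smallrna": int((state["de_small"]["padj"].astype(float)
                              < cfg.alpha_de).sum()),
        "n_de_mrna": int((state["de_mrna"]["padj"].astype(float)
                          < cfg.alpha_de).sum()),
        "n_edges_kept": int(len(state.get("edges_kept", []))),
        "n_clusters": int(len(state["clusters"].sizes)),
        "pca_pc1_variance_fraction": float(state["pca_varfrac"][0]),
    }
    if "concordant" in state:
        summary["n_concordant_proteins"] = int(len(state["concordant"]))
    if bundle.truth is not None:
        recovery = recovery_report(state, bundle)
        summary.update(recovery)
        with open(outdir / "recovery.json", "w") as fh:
            json.dump(recovery, fh, indent=2, sort_keys=True)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _versions() -> dict:
    import networkx
    import scipy
    import sklearn
    import statsmodels

    from . import __version__
    return {"cardiomir": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
            "sklearn": sklearn.__version__, "networkx": networkx.__version__}
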