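"""Synthetic multi-omic study generator.

Emulates the statistical structure the downstream analysis assumes: a
small-RNA cohort and a larger mRNA cohort spanning gestational weeks 8-19
with a shared-heart subset, negative-binomial counts whose log2 mean is
linear (or template-shaped) in age, planted miRNA->mRNA repression that
induces negative Pearson correlation over the shared samples, a 3-vs-3
protein comparison at weeks 10 and 18 with direction-concordant shifts, and
metabolite gene sets enriched for genes moving in one direction.  Ground
truth (DE flags and slopes, planted/decoy edges, cluster templates, protein
concordance, set directions) is exported alongside every dataset.

Counts: NB(mean, dispersion) with variance mu + alpha*mu^2 and
log2 mean_gi = baseline_g + profile_g(age_i) + log2(libsize_i); the
repression term subtracts repression_strength * standardized regulator
latent signal from a target's log2 mean in each shared sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_AGE_BIN_EDGES
from .datatypes import CountMatrix, GeneSetCollection, SampleTable, TargetMap

LN2 = np.log(2.0)

#: Six age-bin template z-profiles (bin centers of the default age bins):
#: monotone up, up with a mid-gestation dip, monotone down, rise-then-fall
#: peaking at week 15, fall-then-rise, and an early peak with late decline.
TEMPLATE_SHAPES = {
    1: [-1.5, -0.9, -0.3, 0.3, 0.9, 1.5],
    2: [-0.8, 1.1, -1.3, 0.0, 0.7, 1.4],
    3: [1.5, 0.9, 0.3, -0.3, -0.9, -1.5],
    4: [-1.3, -0.5, 0.5, 1.3, 0.8, -0.8],
    5: [1.3, 0.3, -0.9, -1.2, -0.2, 0.7],
    6: [0.1, 1.2, 0.9, -0.2, -1.6, -0.4],
}


def _standardize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    return (v - v.mean()) / v.std(ddof=0)


def template_profiles() -> pd.DataFrame:
    """The planted templates, standardized to mean 0 / SD 1 across bins."""
    return pd.DataFrame({k: _standardize(v) for k, v in TEMPLATE_SHAPES.items()}).T


DEFAULT_SUBTYPE_PROPORTIONS = {
    "miRNA": 0.20, "piRNA": 0.30, "circRNA": 0.35,
    "snoRNA": 0.07, "snRNA": 0.04, "tRNA": 0.04,
}
# log2 offsets on baseline expression so read-count composition is dominated
# by circRNA and piRNA, as in fetal-heart small RNAomes
SUBTYPE_LOG2_OFFSET = {
    "miRNA": 1.0, "piRNA": 1.5, "circRNA": 2.0,
    "snoRNA": 0.0, "snRNA": 0.0, "tRNA": 0.0,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic multi-omic generator."""

    n_samples_smallrna: int = 37
    n_samples_mrna: int = 53
    n_shared_samples: int = 30
    age_range: tuple[float, float] = (8.0, 19.0)

    n_mirna: int = 300
    n_mrna: int = 2000
    n_protein: int = 250
    subtype_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_PROPORTIONS))

    fraction_de: float = 0.3
    slope_range: tuple[float, float] = (0.15, 0.35)  # |log2 / week|
    nb_dispersion: float = 0.1
    libsize_range: tuple[float, float] = (0.5, 2.0)  # log-uniform, 4-fold
    baseline_log2_range: tuple[float, float] = (5.0, 9.0)
    batch_effect: float = 0.0  # log2 shift of the second mRNA batch

    n_true_edges: int = 150
    n_decoy_edges: int = 350
    repression_strength: float = 1.0  # log2 decrease per SD of regulator signal

    members_per_template: int = 25
    template_amplitude: float = 1.5  # log2 units per template z-unit

    protein_ages: tuple[float, float] = (10.0, 18.0)
    n_per_protein_group: int = 3
    protein_effect: float = 2.0     # log2 group shift of a concordant protein
    protein_sigma: float = 0.3      # within-group SD, log2 units
    concordance_fraction: float = 0.8
    protein_missing_rate: float = 0.05
    n_protein_from_targets: int = 60

    n_gene_sets: int = 60
    set_size_range: tuple[int, int] = (5, 80)
    fraction_directional: float = 0.3
    gene_set_bias: float = 0.8  # P(member drawn from the directional pool)

    seed: int = 0

    def __post_init__(self) -> None:
        props = self.subtype_proportions
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        if self.n_shared_samples > min(self.n_samples_smallrna, self.n_samples_mrna):
            raise ValueError("n_shared_samples exceeds a cohort size")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age range must satisfy lo < hi")
        for name in ("n_samples_smallrna", "n_samples_mrna", "n_shared_samples",
                     "n_mirna", "n_mrna", "n_protein", "n_true_edges",
                     "n_decoy_edges", "members_per_template", "n_gene_sets"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_true_edges + self.n_decoy_edges > self.n_mirna * self.n_mrna:
            raise ValueError("more edges requested than miRNA x mRNA pairs")
        if not 0 <= self.fraction_de <= 1:
            raise ValueError("fraction_de must be in [0, 1]")
        if self.n_protein > self.n_mrna:
            raise ValueError("proteins are a subset of mRNA genes: "
                             "n_protein must be <= n_mrna")

    @property
    def n_smallrna_total(self) -> int:
        return int(round(self.n_mirna / self.subtype_proportions["miRNA"]))


@dataclass
class GroundTruth:
    """Planted truth sufficient to score recovery without the config."""

    features: pd.DataFrame   # layer, subtype, is_de, true_slope, template_id, true_direction
    edges: pd.DataFrame      # mirna_id, mrna_id, kind, repression_strength
    proteins: pd.DataFrame   # protein_id, mrna_id, effect, concordant, direction
    gene_sets: pd.DataFrame  # set_id, direction, size

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.features.to_csv(outdir / "ground_truth_features.tsv", sep="\t",
                             index_label="feature_id", na_rep="NA",
                             float_format="%.10g")
        self.edges.to_csv(outdir / "ground_truth_edges.tsv", sep="\t",
                          index=False, na_rep="NA", float_format="%.10g")
        self.proteins.to_csv(outdir / "ground_truth_proteins.tsv", sep="\t",
                             index=False, na_rep="NA", float_format="%.10g")
        self.gene_sets.to_csv(outdir / "ground_truth_gene_sets.tsv", sep="\t",
                              index=False, na_rep="NA", float_format="%.10g")


@dataclass
class SyntheticStudy:
    smallrna: CountMatrix
    mrna: CountMatrix
    samples: SampleTable
    target_map: TargetMap
    protein_groups: dict[str, pd.DataFrame]  # group label -> protein x sample
    protein_group_labels: pd.Series          # sample -> group label
    gene_sets: GeneSetCollection
    truth: GroundTruth
    shared_samples: list[str]


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def simulate_ages(n: int, age_range=(8.0, 19.0), seed=None) -> np.ndarray:
    """n gestational ages drawn uniformly over the range, sorted ascending."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = age_range
    if not lo < hi:
        raise ValueError("age range must satisfy lo < hi")
    rng = np.random.default_rng(seed)
    return np.sort(rng.uniform(lo, hi, size=n))


def _nb_counts(rng, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB draw with variance mu + alpha*mu^2 (Poisson limit at alpha -> 0)."""
    mean = np.clip(mean, 1e-12, None)
    if alpha < 1e-10:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _template_mean(ages: np.ndarray, template_z: np.ndarray) -> np.ndarray:
    centers = np.array([(DEFAULT_AGE_BIN_EDGES[i] + DEFAULT_AGE_BIN_EDGES[i + 1]) / 2
                        for i in range(len(DEFAULT_AGE_BIN_EDGES) - 1)])
    return np.interp(ages, centers, template_z)


def _covers_bins(ages: np.ndarray, edges=DEFAULT_AGE_BIN_EDGES) -> bool:
    idx = np.minimum(np.searchsorted(edges, ages, side="right") - 1,
                     len(edges) - 2)
    return len(set(idx)) == len(edges) - 1


def simulate_cohort(cfg: SimulationConfig, seed=None) -> tuple[SampleTable, list[str], list[str], list[str]]:
    """Heart-level metadata for both cohorts plus the shared subset.

    Returns (samples, smallrna_ids, mrna_ids, shared_ids).  Hearts carrying
    both layers model the cross-cohort matching the analysis requires.
    Ages are uniform over the gestational window, redrawn (rarely) until each
    cohort represents every age bin -- mirroring an enrolment design that
    covers the whole window.
    """
    rng = np.random.default_rng(seed)
    n_total = (cfg.n_samples_smallrna + cfg.n_samples_mrna
               - cfg.n_shared_samples)
    ids = [f"H{i + 1:03d}" for i in range(n_total)]
    covers = cfg.age_range == (8.0, 19.0)  # bins only defined on the window
    for _ in range(1000):
        ages = simulate_ages(n_total, cfg.age_range, seed=rng)
        perm = rng.permutation(n_total)
        if not covers:
            break
        small_idx = perm[:cfg.n_samples_smallrna]
        mrna_idx = np.concatenate([perm[:cfg.n_shared_samples],
                                   perm[cfg.n_samples_smallrna:]])
        if _covers_bins(ages[small_idx]) and _covers_bins(ages[mrna_idx]):
            break
    shared = sorted(ids[i] for i in perm[:cfg.n_shared_samples])
    small_only = sorted(
        ids[i] for i in perm[cfg.n_shared_samples:cfg.n_samples_smallrna])
    mrna_only = sorted(ids[i] for i in perm[cfg.n_samples_smallrna:])
    layers = {}
    for s in shared:
        layers[s] = "smallRNA;mRNA"
    for s in small_only:
        layers[s] = "smallRNA"
    for s in mrna_only:
        layers[s] = "mRNA"
    table = pd.DataFrame({
        "gestational_age": ages,
        "sex": rng.choice(["F", "M"], size=n_total),
        "batch": [f"b{1 + i % 2}" for i in range(n_total)],
        "layers": [layers[i] for i in ids],
    }, index=pd.Index(ids, name="sample_id"))
    smallrna_ids = sorted(shared + small_only)
    mrna_ids = sorted(shared + mrna_only)
    return SampleTable(table), smallrna_ids, mrna_ids, shared


def simulate_small_rna(cfg: SimulationConfig, samples: SampleTable,
                       sample_ids, seed=None
                       ) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Small-RNA count matrix with planted linear-slope DE features and
    template-shaped miRNA clusters.

    Returns (counts, per-feature truth, latent log2 means without library
    size) -- the latent matrix feeds the repression of mRNA targets.
    """
    rng = np.random.default_rng(seed)
    ages = samples.ages(sample_ids)
    age_c = ages - np.mean(cfg.age_range)
    n_total = cfg.n_smallrna_total

    subtypes = []
    for st, prop in cfg.subtype_proportions.items():
        n_st = cfg.n_mirna if st == "miRNA" else int(round(prop * n_total))
        subtypes += [st] * n_st
    subtypes = subtypes[:n_total] + ["other"] * max(0, n_total - len(subtypes))
    feat_ids, kinds = [], {}
    counters: dict[str, int] = {}
    for st in subtypes:
        counters[st] = counters.get(st, 0) + 1
        prefix = {"miRNA": "hsa-miR-sim", "piRNA": "piR-sim",
                  "circRNA": "circ-sim", "snoRNA": "SNORD-sim",
                  "snRNA": "RNU-sim", "tRNA": "tRNA-sim"}.get(st, "sRNA-sim")
        feat_ids.append(f"{prefix}-{counters[st]:04d}")
        kinds[feat_ids[-1]] = st

    truth = pd.DataFrame({
        "layer": "smallRNA",
        "subtype": [kinds[f] for f in feat_ids],
        "is_de": False,
        "true_slope": 0.0,
        "template_id": pd.array([pd.NA] * len(feat_ids), dtype="Int64"),
        "true_direction": 0,
    }, index=pd.Index(feat_ids, name="feature_id"))

    mirna_ids = [f for f in feat_ids if kinds[f] == "miRNA"]
    n_template = 6 * cfg.members_per_template
    if n_template > len(mirna_ids):
        raise ValueError("members_per_template too large for n_mirna")
    template_members = mirna_ids[:n_template]
    templates = template_profiles()
    for t in range(6):
        members = template_members[t * cfg.members_per_template:
                                   (t + 1) * cfg.members_per_template]
        truth.loc[members, "template_id"] = t + 1
        truth.loc[members, "is_de"] = True
        truth.loc[members, "true_slope"] = np.nan

    # linear-slope DE among the remaining features (all subtypes)
    remaining = [f for f in feat_ids if f not in set(template_members)]
    n_de = int(round(cfg.fraction_de * len(remaining)))
    de_feats = list(rng.choice(remaining, size=n_de, replace=False))
    lo, hi = cfg.slope_range
    slopes = rng.uniform(lo, hi, size=n_de) * rng.choice([-1.0, 1.0], size=n_de)
    truth.loc[de_feats, "is_de"] = True
    truth.loc[de_feats, "true_slope"] = slopes
    truth.loc[de_feats, "true_direction"] = np.sign(slopes).astype(int)

    baselines = rng.uniform(*cfg.baseline_log2_range, size=len(feat_ids))
    baselines += np.array([SUBTYPE_LOG2_OFFSET.get(kinds[f], 0.0)
                           for f in feat_ids])
    latent = np.tile(baselines[:, None], (1, len(sample_ids)))
    pos = {f: i for i, f in enumerate(feat_ids)}
    for f in de_feats:
        latent[pos[f]] += truth.at[f, "true_slope"] * age_c
    for t in range(6):
        shape = _template_mean(ages, templates.loc[t + 1].to_numpy())
        for f in template_members[t * cfg.members_per_template:
                                  (t + 1) * cfg.members_per_template]:
            latent[pos[f]] += cfg.template_amplitude * shape

    libsizes = np.exp(rng.uniform(np.log(cfg.libsize_range[0]),
                                  np.log(cfg.libsize_range[1]),
                                  size=len(sample_ids)))
    mean = np.exp2(latent) * libsizes[None, :]
    counts = _nb_counts(rng, mean, cfg.nb_dispersion)
    cm = CountMatrix(
        pd.DataFrame(counts, index=feat_ids, columns=list(sample_ids)),
        pd.DataFrame({"subtype": [kinds[f] for f in feat_ids],
                      "uniquely_mapped": True}, index=feat_ids))
    latent_df = pd.DataFrame(latent, index=feat_ids, columns=list(sample_ids))
    return cm, truth, latent_df


def simulate_target_map(cfg: SimulationConfig, regulator_ids, target_pool,
                        seed=None) -> tuple[TargetMap, pd.DataFrame]:
    """Planted repressive edges plus decoy edges (disjoint pairs).

    Regulators are drawn from ``regulator_ids`` (DE miRNAs); each edge gets a
    distinct target from ``target_pool`` so planted and decoy targets never
    overlap.
    """
    rng = np.random.default_rng(seed)
    n_edges = cfg.n_true_edges + cfg.n_decoy_edges
    if n_edges > len(regulator_ids) * len(target_pool):
        raise ValueError("infeasible edge counts for the given pools")
    if n_edges > len(target_pool):
        raise ValueError(f"need {n_edges} distinct targets, pool has "
                         f"{len(target_pool)}")
    regs = rng.choice(list(regulator_ids), size=n_edges, replace=True)
    targets = rng.choice(list(target_pool), size=n_edges, replace=False)
    kind = ["planted"] * cfg.n_true_edges + ["decoy"] * cfg.n_decoy_edges
    edges = pd.DataFrame({
        "mirna_id": regs, "mrna_id": targets, "kind": kind,
        "repression_strength": [cfg.repression_strength] * cfg.n_true_edges
        + [0.0] * cfg.n_decoy_edges,
    })
    return TargetMap(set(zip(edges["mirna_id"], edges["mrna_id"]))), edges


def simulate_mrna_with_repression(cfg: SimulationConfig, samples: SampleTable,
                                  sample_ids, shared_ids,
                                  mirna_latent: pd.DataFrame,
                                  edges: pd.DataFrame, seed=None
                                  ) -> tuple[CountMatrix, pd.DataFrame]:
    """mRNA counts: linear-slope DE genes plus planted repression targets.

    A planted target's log2 mean is reduced by repression_strength times the
    standardized latent signal of its regulator in each shared sample;
    decoy-edge targets stay unmodified null genes.
    """
    rng = np.random.default_rng(seed)
    ages = samples.ages(sample_ids)
    age_c = ages - np.mean(cfg.age_range)
    feat_ids = [f"GENE{i + 1:05d}" for i in range(cfg.n_mrna)]
    unknown = set(edges["mrna_id"]) - set(feat_ids)
    if unknown:
        raise ValueError(f"edge references unknown mRNA feature "
                         f"{sorted(unknown)[0]!r}")
    unknown_m = set(edges["mirna_id"]) - set(mirna_latent.index)
    if unknown_m:
        raise ValueError(f"edge references unknown miRNA feature "
                         f"{sorted(unknown_m)[0]!r}")

    truth = pd.DataFrame({
        "layer": "mRNA", "subtype": "mRNA", "is_de": False,
        "true_slope": 0.0,
        "template_id": pd.array([pd.NA] * cfg.n_mrna, dtype="Int64"),
        "true_direction": 0,
    }, index=pd.Index(feat_ids, name="feature_id"))

    edge_targets = set(edges["mrna_id"])
    free = [f for f in feat_ids if f not in edge_targets]
    n_de = int(round(cfg.fraction_de * cfg.n_mrna))
    n_de = min(n_de, len(free))
    de_feats = list(rng.choice(free, size=n_de, replace=False))
    lo, hi = cfg.slope_range
    slopes = rng.uniform(lo, hi, size=n_de) * rng.choice([-1.0, 1.0], size=n_de)
    truth.loc[de_feats, "is_de"] = True
    truth.loc[de_feats, "true_slope"] = slopes
    truth.loc[de_feats, "true_direction"] = np.sign(slopes).astype(int)

    baselines = rng.uniform(*cfg.baseline_log2_range, size=cfg.n_mrna)
    latent = np.tile(baselines[:, None], (1, len(sample_ids)))
    pos = {f: i for i, f in enumerate(feat_ids)}
    for f, s in zip(de_feats, slopes):
        latent[pos[f]] += s * age_c

    shared = [s for s in sample_ids if s in set(shared_ids)]
    shared_cols = [list(sample_ids).index(s) for s in shared]
    planted = edges[edges["kind"] == "planted"]
    for _, e in planted.iterrows():
        reg = mirna_latent.loc[e["mirna_id"], shared].to_numpy(float)
        sd = reg.std(ddof=0)
        if sd == 0 or e["repression_strength"] == 0:
            continue
        signal = (reg - reg.mean()) / sd
        g = pos[e["mrna_id"]]
        latent[g, shared_cols] -= e["repression_strength"] * signal
        truth.at[e["mrna_id"], "is_de"] = True
        truth.at[e["mrna_id"], "true_slope"] = np.nan
        # induced direction opposes the regulator's slope
        reg_trend = np.polyfit(samples.ages(shared), reg, 1)[0]
        truth.at[e["mrna_id"], "true_direction"] = int(-np.sign(reg_trend))

    if cfg.batch_effect != 0.0:
        batch = samples.table.loc[list(sample_ids), "batch"]
        latent[:, (batch == "b2").to_numpy()] += cfg.batch_effect

    libsizes = np.exp(rng.uniform(np.log(cfg.libsize_range[0]),
                                  np.log(cfg.libsize_range[1]),
                                  size=len(sample_ids)))
    mean = np.exp2(latent) * libsizes[None, :]
    counts = _nb_counts(rng, mean, cfg.nb_dispersion)
    cm = CountMatrix(
        pd.DataFrame(counts, index=feat_ids, columns=list(sample_ids)),
        pd.DataFrame({"subtype": "mRNA", "uniquely_mapped": True},
                     index=feat_ids))
    return cm, truth


def simulate_proteins(cfg: SimulationConfig, mrna_truth: pd.DataFrame,
                      seed=None) -> tuple[dict[str, pd.DataFrame], pd.Series, pd.DataFrame]:
    """3-vs-3 protein abundances at two gestational ages.

    Proteins are a subset of mRNA genes, preferring planted targets so the
    tripartite layer has paths to find.  A concordant protein shifts by
    ``protein_effect`` in its gene's true direction between the two groups;
    the non-concordant remainder shifts oppositely or not at all.  A small
    fraction of proteins is knocked out in one sample to exercise the
    common-protein filter.
    """
    rng = np.random.default_rng(seed)
    target_genes = list(mrna_truth.index[mrna_truth["is_de"]
                                         & mrna_truth["true_slope"].isna()])
    n_from_targets = min(cfg.n_protein_from_targets, len(target_genes),
                         cfg.n_protein)
    chosen = list(rng.choice(target_genes, size=n_from_targets, replace=False))
    rest_pool = [g for g in mrna_truth.index if g not in set(chosen)]
    chosen += list(rng.choice(rest_pool, size=cfg.n_protein - n_from_targets,
                              replace=False))
    chosen = sorted(chosen)

    groups = {f"wk{int(a)}": [f"P{int(a)}_{j + 1}" for j in
                              range(cfg.n_per_protein_group)]
              for a in cfg.protein_ages}
    label_of = {s: g for g, ss in groups.items() for s in ss}
    group_names = list(groups)

    prot_truth_rows = []
    tables = {g: pd.DataFrame(index=chosen, columns=groups[g], dtype=float)
              for g in group_names}
    for gene in chosen:
        direction = int(mrna_truth.at[gene, "true_direction"])
        concordant = False
        delta = 0.0
        if direction != 0:
            u = rng.random()
            if u < cfg.concordance_fraction:
                concordant, delta = True, cfg.protein_effect * direction
            elif u < cfg.concordance_fraction + (1 - cfg.concordance_fraction) / 2:
                delta = -cfg.protein_effect * direction
        base = rng.uniform(20.0, 30.0)
        means = {group_names[0]: base - delta / 2.0,
                 group_names[1]: base + delta / 2.0}
        for g in group_names:
            tables[g].loc[gene] = rng.normal(means[g], cfg.protein_sigma,
                                             size=cfg.n_per_protein_group)
        prot_truth_rows.append((f"prot_{gene}", gene, delta, concordant,
                                direction if concordant else 0))
    # rename protein rows so the protein/mRNA identifier join is explicit
    for g in group_names:
        tables[g].index = [f"prot_{gene}" for gene in chosen]
    missing_mask = rng.random(len(chosen)) < cfg.protein_missing_rate
    for i in np.flatnonzero(missing_mask):
        g = group_names[int(rng.integers(len(group_names)))]
        col = tables[g].columns[int(rng.integers(cfg.n_per_protein_group))]
        tables[g].iloc[i, tables[g].columns.get_loc(col)] = np.nan

    labels = pd.Series(label_of)
    truth = pd.DataFrame(prot_truth_rows,
                         columns=["protein_id", "mrna_id", "effect",
                                  "concordant", "direction"])
    return tables, labels, truth


def simulate_gene_sets(cfg: SimulationConfig, mrna_truth: pd.DataFrame,
                       seed=None) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Metabolite-style gene sets: "up"/"down" sets oversample genes whose
    true direction matches; "null" sets sample the universe uniformly."""
    rng = np.random.default_rng(seed)
    universe = list(mrna_truth.index)
    up_pool = list(mrna_truth.index[mrna_truth["true_direction"] > 0])
    down_pool = list(mrna_truth.index[mrna_truth["true_direction"] < 0])
    n_dir = int(round(cfg.fraction_directional * cfg.n_gene_sets / 2))
    directions = (["up"] * n_dir + ["down"] * n_dir
                  + ["null"] * (cfg.n_gene_sets - 2 * n_dir))
    sets, truth_rows = {}, []
    lo, hi = cfg.set_size_range
    for i, direction in enumerate(directions):
        k = int(rng.integers(lo, hi + 1))
        pool = {"up": up_pool, "down": down_pool, "null": universe}[direction]
        members: set[str] = set()
        if direction != "null":
            n_biased = min(int(rng.binomial(k, cfg.gene_set_bias)), len(pool))
            members |= set(rng.choice(pool, size=n_biased, replace=False))
        fill = [g for g in universe if g not in members]
        members |= set(rng.choice(fill, size=k - len(members), replace=False))
        name = f"metabolite_{i + 1:03d}"
        sets[name] = members
        truth_rows.append((name, direction, k))
    gsc = GeneSetCollection(sets, {n: f"synthetic {d} set"
                                   for (n, d, _) in truth_rows})
    truth = pd.DataFrame(truth_rows, columns=["set_id", "direction", "size"])
    return gsc, truth


def simulate_zprofiles(n_per_template: int = 25, noise_sd: float = 0.2,
                       template_ids=tuple(range(1, 7)), seed=None
                       ) -> tuple[pd.DataFrame, pd.Series]:
    """Standalone z-profile generator for the pattern-clustering stage.

    Each feature is its template plus bin-wise Gaussian noise, re-standardized
    across bins.  Returns (profiles, true template labels).
    """
    rng = np.random.default_rng(seed)
    templates = template_profiles()
    rows, labels = [], []
    ids = []
    for t in template_ids:
        base = templates.loc[t].to_numpy()
        for j in range(n_per_template):
            noisy = base + rng.normal(0.0, noise_sd, size=base.size)
            rows.append(_standardize(noisy))
            labels.append(t)
            ids.append(f"T{t}_f{j + 1:03d}")
    from .clustering import bin_labels
    profiles = pd.DataFrame(rows, index=ids, columns=bin_labels())
    return profiles, pd.Series(labels, index=ids, name="template_id")


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def simulate_study(cfg: SimulationConfig | None = None, seed=None) -> SyntheticStudy:
    """Generate the complete synthetic study with exported ground truth.

    All stages draw from child seeds of one integer-seeded generator, so a
    fixed (config, seed) pair reproduces every table bit-for-bit.
    """
    cfg = cfg or SimulationConfig()
    root = np.random.default_rng(cfg.seed if seed is None else seed)
    seeds = root.integers(0, 2**31 - 1, size=8)

    samples, small_ids, mrna_ids, shared = simulate_cohort(cfg, seed=seeds[0])
    smallrna, truth_small, latent = simulate_small_rna(cfg, samples, small_ids,
                                                       seed=seeds[1])
    # regulators: linear-slope DE miRNAs (monotone, detectable by the
    # continuous-age model)
    regs = truth_small.index[(truth_small["subtype"] == "miRNA")
                             & truth_small["is_de"]
                             & truth_small["true_slope"].notna()]
    mrna_target_pool = [f"GENE{i + 1:05d}" for i in range(cfg.n_mrna)]
    tm, edges = simulate_target_map(cfg, list(regs), mrna_target_pool,
                                    seed=seeds[2])
    # decoy targets must be null genes: simulate_mrna_with_repression assigns
    # its own DE genes outside the edge-target pool
    mrna, truth_mrna = simulate_mrna_with_repression(
        cfg, samples, mrna_ids, shared, latent, edges, seed=seeds[3])
    protein_tables, protein_labels, truth_prot = simulate_proteins(
        cfg, truth_mrna, seed=seeds[4])
    gsc, truth_sets = simulate_gene_sets(cfg, truth_mrna, seed=seeds[5])

    truth = GroundTruth(
        features=pd.concat([truth_small, truth_mrna]),
        edges=edges, proteins=truth_prot, gene_sets=truth_sets)
    return SyntheticStudy(
        smallrna=smallrna, mrna=mrna, samples=samples, target_map=tm,
        protein_groups=protein_tables, protein_group_labels=protein_labels,
        gene_sets=gsc, truth=truth, shared_samples=list(shared))
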