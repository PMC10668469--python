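"""Anti-correlation miRNA-mRNA network construction and multi-omic
integration.

Predicted target pairs whose endpoints are both differentially expressed are
scored by Pearson correlation over the shared samples; significantly
anti-correlated pairs (p < 0.05 and r < 0, strict) form the regulatory
network, optionally tightened by top-fraction or hard r cuts.  Differentially
abundant proteins concordant with their mRNA's direction extend the network
into a tripartite miRNA -> mRNA -> protein graph whose every path satisfies
the repression polarity (up-miRNA -> down-mRNA -> depleted protein, or the
mirror).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import TargetMap

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["mirna_id", "mrna_id", "r", "p", "n", "mrna_direction"]


# ---------------------------------------------------------------------------
# pair construction and correlation
# ---------------------------------------------------------------------------

def candidate_pairs(de_mirnas, de_mrnas, tm: TargetMap) -> list[tuple[str, str]]:
    """Predicted target edges whose miRNA and mRNA are both DE."""
    mirnas, mrnas = set(de_mirnas), set(de_mrnas)
    return sorted((m, g) for m, g in tm.edges if m in mirnas and g in mrnas)


def pearson_edge(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p from t = r*sqrt((n-2)/(1-r^2))
    on n-2 degrees of freedom; |r| = 1 yields p = 0."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n != y.size:
        raise ValueError("vectors must have equal length")
    if n < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance vector")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * scipy.stats.t.sf(abs(t), n - 2)
    return r, float(p)


def correlate_pairs(pairs, norm_mirna: pd.DataFrame, norm_mrna: pd.DataFrame,
                    shared_samples) -> pd.DataFrame:
    """One CorrelationEdge row per candidate pair, over the shared samples.

    Pairs with a zero-variance vector are dropped with a warning.
    """
    shared = list(shared_samples)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    missing = (set(shared) - set(norm_mirna.columns)) | (set(shared) - set(norm_mrna.columns))
    if missing:
        raise ValueError(f"shared samples missing from matrices: {sorted(missing)}")
    mi = norm_mirna[shared]
    mr = norm_mrna[shared]
    rows = []
    n_dropped = 0
    for m, g in pairs:
        if m not in mi.index:
            raise ValueError(f"miRNA {m!r} absent from the miRNA matrix")
        if g not in mr.index:
            raise ValueError(f"mRNA {g!r} absent from the mRNA matrix")
        try:
            r, p = pearson_edge(mi.loc[m].to_numpy(), mr.loc[g].to_numpy())
        except ValueError:
            n_dropped += 1
            continue
        rows.append((m, g, r, p, len(shared), ""))
    if n_dropped:
        logger.warning("correlate_pairs: dropped %d pair(s) with zero variance",
                       n_dropped)
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


# ---------------------------------------------------------------------------
# edge filters (all strict inequalities)
# ---------------------------------------------------------------------------

def filter_anticorrelated(edges: pd.DataFrame, p_max: float = 0.05,
                          r_max: float = 0.0) -> pd.DataFrame:
    """Retain exactly the edges with p < p_max and r < r_max."""
    keep = (edges["p"] < p_max) & (edges["r"] < r_max)
    return edges[keep].reset_index(drop=True)


def partition_by_mrna_direction(edges: pd.DataFrame, mrna_de: pd.DataFrame
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split edges by the sign of the target mRNA's log2 fold change."""
    missing = set(edges["mrna_id"]) - set(mrna_de.index)
    if missing:
        raise ValueError(f"mRNA(s) absent from the DE table: {sorted(missing)[:3]}")
    lfc = mrna_de["log2fc"].astype(float).reindex(edges["mrna_id"]).to_numpy()
    n_zero = int((lfc == 0).sum())
    if n_zero:
        logger.warning("partition_by_mrna_direction: dropped %d edge(s) with "
                       "log2fc exactly 0", n_zero)
    up = edges[lfc > 0].copy()
    up["mrna_direction"] = "up"
    down = edges[lfc < 0].copy()
    down["mrna_direction"] = "down"
    return up.reset_index(drop=True), down.reset_index(drop=True)


def select_top_fraction(edges: pd.DataFrame, fraction: float = 0.05) -> pd.DataFrame:
    """The ceil(fraction*N) most negatively correlated edges.

    Ordering: ascending r, ties by smaller p, then lexicographic
    (mirna_id, mrna_id).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if edges.empty:
        return edges.copy()
    k = math.ceil(fraction * len(edges))
    ordered = edges.sort_values(["r", "p", "mirna_id", "mrna_id"],
                                kind="stable")
    return ordered.head(k).reset_index(drop=True)


def threshold_edges(edges: pd.DataFrame, r_cut: float) -> pd.DataFrame:
    """Retain edges with r strictly below a negative cut (figure-level view)."""
    if r_cut >= 0:
        raise ValueError(f"r_cut must be negative, got {r_cut}")
    return edges[edges["r"] < r_cut].reset_index(drop=True)


# ---------------------------------------------------------------------------
# protein layer
# ---------------------------------------------------------------------------

def common_protein_filter(*group_tables: pd.DataFrame) -> pd.DataFrame:
    """Retain proteins detected (non-missing) in every sample of every group
    table; returns the concatenated abundance matrix."""
    if sum(t.shape[1] for t in group_tables) < 2:
        raise ValueError("need at least 2 samples")
    merged = pd.concat(group_tables, axis=1, join="outer")
    dup = merged.columns[merged.columns.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample id across groups: {dup[0]!r}")
    keep = merged.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("common_protein_filter: dropped %d of %d proteins not "
                    "detected in all samples", n_dropped, merged.shape[0])
    return merged[keep]


def concordant_pairs(protein_de: pd.DataFrame, mrna_de: pd.DataFrame,
                     alpha: float = 0.05, id_map: dict[str, str] | None = None
                     ) -> pd.DataFrame:
    """Proteins whose differential abundance agrees in direction with their
    mRNA's differential expression.

    Criteria: protein raw p < alpha, mRNA padj < alpha, and matching log2fc
    sign.  ``id_map`` maps protein ids to mRNA ids when identifiers differ
    (default: identity).
    """
    rows = []
    for prot in protein_de.index:
        gene = (id_map or {}).get(prot, prot)
        if gene not in mrna_de.index:
            continue
        p_lfc = protein_de.at[prot, "log2fc"]
        p_p = protein_de.at[prot, "p"]
        m_lfc = mrna_de.at[gene, "log2fc"]
        m_padj = mrna_de.at[gene, "padj"]
        if pd.isna(p_p) or pd.isna(m_padj) or pd.isna(p_lfc) or pd.isna(m_lfc):
            continue
        if (float(p_p) < alpha and float(m_padj) < alpha
                and np.sign(float(p_lfc)) == np.sign(float(m_lfc))
                and float(p_lfc) != 0):
            rows.append((prot, gene, float(p_lfc), float(p_p),
                         float(m_lfc), float(m_padj),
                         "up" if float(p_lfc) > 0 else "down"))
    return pd.DataFrame(rows, columns=["protein_id", "mrna_id", "protein_log2fc",
                                       "protein_p", "mrna_log2fc", "mrna_padj",
                                       "direction"])


# ---------------------------------------------------------------------------
# tripartite network
# ---------------------------------------------------------------------------

POLARITIES = {
    # down-regulated miRNA releases its target: mRNA up, protein enriched
    "down-miR:up-mRNA:enriched": ("down", "up", "up"),
    # up-regulated miRNA represses its target: mRNA down, protein depleted
    "up-miR:down-mRNA:depleted": ("up", "down", "down"),
}


def build_tripartite(edges: pd.DataFrame, concordant: pd.DataFrame,
                     mirna_de: pd.DataFrame, polarity: str
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the miRNA -> mRNA -> protein network for one polarity.

    Keeps only miRNA-mRNA edges whose target carries a concordant protein of
    the requested direction and whose miRNA moves the opposite way; every
    retained path is re-validated against the polarity before returning.
    Returns (nodes, edges) tables ready for :func:`cardiomir.io.write_network`.
    """
    if polarity not in POLARITIES:
        raise ValueError(f"unknown polarity {polarity!r}; "
                         f"expected one of {sorted(POLARITIES)}")
    mir_dir, mrna_dir, prot_dir = POLARITIES[polarity]
    prot = concordant[concordant["direction"] == prot_dir]
    prot_by_gene = prot.groupby("mrna_id")

    node_rows, edge_rows = [], []
    seen_nodes = set()
    for _, e in edges.iterrows():
        m, g = e["mirna_id"], e["mrna_id"]
        if g not in prot_by_gene.groups:
            continue
        if m not in mirna_de.index:
            raise ValueError(f"miRNA {m!r} absent from the miRNA DE table")
        mir_lfc = float(mirna_de.at[m, "log2fc"])
        if (mir_dir == "down") != (mir_lfc < 0):
            continue
        for _, prow in prot_by_gene.get_group(g).iterrows():
            # re-validate the full path polarity
            m_up = mir_lfc > 0
            g_up = float(prow["mrna_log2fc"]) > 0
            p_up = float(prow["protein_log2fc"]) > 0
            if (m_up, g_up, p_up) != (mir_dir == "up", mrna_dir == "up",
                                      prot_dir == "up"):
                raise ValueError(
                    f"polarity violation on path {m} -> {g} -> "
                    f"{prow['protein_id']}")
            if m not in seen_nodes:
                node_rows.append((m, "miRNA", mir_dir, mir_lfc, np.nan))
                seen_nodes.add(m)
            if g not in seen_nodes:
                node_rows.append((g, "mRNA", mrna_dir,
                                  float(prow["mrna_log2fc"]), np.nan))
                seen_nodes.add(g)
            pid = prow["protein_id"]
            if pid not in seen_nodes:
                node_rows.append((pid, "protein", prot_dir,
                                  float(prow["protein_log2fc"]),
                                  float(prow["protein_p"])))
                seen_nodes.add(pid)
            edge_rows.append((m, g, float(e["r"]), float(e["p"]), "targets"))
            edge_rows.append((g, pid, np.nan, float(prow["protein_p"]),
                              "encodes"))
    nodes = pd.DataFrame(node_rows,
                         columns=["id", "layer", "direction", "log2fc", "p"])
    edge_df = pd.DataFrame(edge_rows,
                           columns=["source", "target", "r", "p", "kind"])
    edge_df = edge_df.drop_duplicates().reset_index(drop=True)
    return nodes, edge_df
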