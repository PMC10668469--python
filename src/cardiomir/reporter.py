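"""Directional reporter-metabolite / gene-set statistics.

Each gene contributes a signed inverse-normal score derived from its
(adjusted) DE p-value and fold-change sign.  A gene set's directional score
is the sum of member scores divided by sqrt(k); significance comes from a
permutation null built by drawing size-k subsets of the full directional
background without replacement, with the add-one estimator
p = (1 + #{Z* >= Z_obs}) / (1 + n_perm).  Up- and down-direction nulls reuse
the same drawn subsets, so flipping every gene's sign swaps the two
directions bit-exactly.  On small backgrounds an exhaustive mode enumerates
every subset instead of sampling.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import GeneSetCollection

logger = logging.getLogger(__name__)

EPS = 1e-12

REPORTER_COLUMNS = ["set_id", "k", "Z_up", "Z_down", "p_up", "p_down",
                    "padj_up", "padj_down", "call", "call_strict", "status"]


def make_gene_stats(mrna_de: pd.DataFrame, genes=None, use_adjusted: bool = True
                    ) -> pd.DataFrame:
    """Build the gene-level input: clamped p-value and fold-change sign.

    Genes with missing statistics or log2fc exactly 0 are excluded (the
    directional statistic needs a sign).
    """
    de = mrna_de if genes is None else mrna_de.loc[mrna_de.index.intersection(list(genes))]
    pcol = "padj" if use_adjusted else "p"
    p = de[pcol].astype(float)
    lfc = de["log2fc"].astype(float)
    keep = p.notna() & lfc.notna() & (lfc != 0)
    n_zero = int((lfc == 0).sum())
    if n_zero:
        logger.warning("make_gene_stats: excluded %d gene(s) with log2fc == 0",
                       n_zero)
    out = pd.DataFrame({
        "p": np.clip(p[keep].to_numpy(), EPS, 1 - EPS),
        "sign": np.sign(lfc[keep]).astype(int),
    }, index=de.index[keep])
    return out


def signed_directional_z(p, sign, direction: str):
    """Signed inverse-normal gene score for one direction.

    For ``up``: p_dir = p/2 when the gene moves up, else 1 - p/2 (mirrored
    for ``down``); z = Phi^-1(1 - p_dir).  A gene strongly moving with the
    tested direction scores high; one moving against it scores negative.
    """
    p = np.asarray(p, float)
    sign = np.asarray(sign)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("p must lie strictly inside (0, 1) after clamping")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    with_dir = sign > 0 if direction == "up" else sign < 0
    p_dir = np.where(with_dir, p / 2.0, 1.0 - p / 2.0)
    z = scipy.stats.norm.isf(p_dir)
    return z if z.shape else float(z)


def set_score(z_values) -> float:
    """Aggregate member scores: Z = sum(z) / sqrt(k)."""
    z = np.asarray(z_values, float)
    if z.size == 0:
        raise ValueError("cannot score an empty gene set")
    return float(z.sum() / sqrt(z.size))


def permutation_pvalue(z_obs: float, background, k: int, n_perm: int = 1000,
                       rng=None, exhaustive: bool = False) -> float:
    """Permutation p-value of an observed set score against random size-k
    subsets of the background scores (drawn without replacement).

    Sampled mode uses the add-one estimator (1 + #{Z* >= Z}) / (1 + n_perm);
    exhaustive mode enumerates all C(n, k) subsets and returns the exact
    fraction #{Z* >= Z} / C(n, k).
    """
    bg = np.asarray(background, float)
    if k > bg.size:
        raise ValueError(f"background of {bg.size} is smaller than k={k}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if exhaustive:
        n_ge = sum(1 for c in combinations(bg, k)
                   if sum(c) / sqrt(k) >= z_obs)
        return n_ge / comb(bg.size, k)
    rng = np.random.default_rng(rng)
    n_ge = 0
    for _ in range(n_perm):
        idx = rng.choice(bg.size, size=k, replace=False)
        if bg[idx].sum() / sqrt(k) >= z_obs:
            n_ge += 1
    return (1 + n_ge) / (1 + n_perm)


def run_reporter(stats: pd.DataFrame, gsc: GeneSetCollection, min_k: int = 5,
                 max_k: int = 500, n_perm: int = 1000, alpha: float = 0.05,
                 figure_alpha: float = 0.01, seed: int | None = 0,
                 exhaustive: bool = False) -> pd.DataFrame:
    """Directional reporter analysis of every set in a collection.

    ``stats`` is the output of :func:`make_gene_stats`.  Sets whose overlap
    with the statistics falls outside [min_k, max_k] are recorded as skipped.
    ``call`` flags the direction with BH-adjusted permutation p < alpha
    (``call_strict`` uses ``figure_alpha``); when both directions pass, the
    smaller adjusted p wins.
    """
    if len(gsc) == 0:
        raise ValueError("gene set collection is empty")
    if stats.empty:
        raise ValueError("gene statistics are empty")
    from .de import adjust_bh  # local import to avoid a cycle

    genes = stats.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    p_all = stats["p"].to_numpy(float)
    sign_all = stats["sign"].to_numpy()
    z_up_all = signed_directional_z(p_all, sign_all, "up")
    z_down_all = signed_directional_z(p_all, sign_all, "down")
    n_genes = genes.size

    rng = np.random.default_rng(seed)
    rows = []
    for set_id, members in gsc:
        member_idx = np.array(sorted(gene_pos[g] for g in members if g in gene_pos),
                              dtype=int)
        k = member_idx.size
        if k < min_k or k > max_k:
            reason = "k<min" if k < min_k else "k>max"
            rows.append([set_id, k, np.nan, np.nan, np.nan, np.nan,
                         np.nan, np.nan, "none", "none", f"skipped:{reason}"])
            continue
        z_up = set_score(z_up_all[member_idx])
        z_down = set_score(z_down_all[member_idx])
        if exhaustive:
            p_up = permutation_pvalue(z_up, z_up_all, k, n_perm, exhaustive=True)
            p_down = permutation_pvalue(z_down, z_down_all, k, n_perm,
                                        exhaustive=True)
        else:
            # one subset stream feeds both directions -> sign-flip symmetry
            n_up = n_down = 0
            sk = sqrt(k)
            for _ in range(n_perm):
                idx = rng.choice(n_genes, size=k, replace=False)
                if z_up_all[idx].sum() / sk >= z_up:
                    n_up += 1
                if z_down_all[idx].sum() / sk >= z_down:
                    n_down += 1
            p_up = (1 + n_up) / (1 + n_perm)
            p_down = (1 + n_down) / (1 + n_perm)
        rows.append([set_id, k, z_up, z_down, p_up, p_down,
                     np.nan, np.nan, "none", "none", "evaluated"])

    res = pd.DataFrame(rows, columns=REPORTER_COLUMNS).set_index("set_id")
    ev = res["status"] == "evaluated"
    res.loc[ev, "padj_up"] = adjust_bh(res.loc[ev, "p_up"].to_numpy(float))
    res.loc[ev, "padj_down"] = adjust_bh(res.loc[ev, "p_down"].to_numpy(float))

    for col, cut in (("call", alpha), ("call_strict", figure_alpha)):
        up_sig = ev & (res["padj_up"].astype(float) < cut)
        down_sig = ev & (res["padj_down"].astype(float) < cut)
        both = up_sig & down_sig
        res.loc[up_sig, col] = "up"
        res.loc[down_sig, col] = "down"
        res.loc[both, col] = np.where(
            res.loc[both, "padj_up"].astype(float)
            <= res.loc[both, "padj_down"].astype(float), "up", "down")
    return res


def random_control_run(mrna_de: pd.DataFrame, n: int, gsc: GeneSetCollection,
                       exclude=None, alpha_de: float = 0.05, seed: int = 0,
                       **reporter_kwargs) -> tuple[list[str], pd.DataFrame]:
    """Reporter run on a random subset of differentially expressed genes.

    Draws ``n`` DE genes (padj < alpha_de) without replacement, optionally
    excluding a gene set (e.g. predicted miRNA targets, reproducing the
    non-target control), and reruns the reporter analysis on that subset.
    """
    padj = mrna_de["padj"].astype(float)
    eligible = mrna_de.index[(padj < alpha_de) & padj.notna()]
    if exclude is not None:
        eligible = eligible.difference(list(exclude))
    if len(eligible) < n:
        raise ValueError(f"only {len(eligible)} eligible genes for a control "
                         f"of size {n}")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(eligible.to_numpy(), size=n, replace=False))
    stats = make_gene_stats(mrna_de, genes=chosen)
    res = run_reporter(stats, gsc, seed=seed, **reporter_kwargs)
    return list(chosen), res
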