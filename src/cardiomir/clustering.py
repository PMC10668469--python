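"""Temporal expression patterns over gestational-age bins.

Features are summarized as z-score profiles across age bins (mean of
log-normalized expression per bin, standardized across bins) and grouped by
hierarchical clustering under correlation distance, with small clusters
dissolved into an explicit "unassigned" pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .config import DEFAULT_AGE_BIN_EDGES
from .datatypes import SampleTable

logger = logging.getLogger(__name__)

UNASSIGNED = 0  # cluster id reserved for features without a stable pattern


def bin_labels(edges=DEFAULT_AGE_BIN_EDGES) -> list[str]:
    return [f"{edges[i]:g}-{edges[i + 1]:g}" for i in range(len(edges) - 1)]


def bin_mean_zscores(norm_log: pd.DataFrame, samples: SampleTable,
                     edges=DEFAULT_AGE_BIN_EDGES) -> tuple[pd.DataFrame, list[str]]:
    """Per-feature z-score profile over age bins.

    Bins are half-open [lo, hi) except the last, which is closed so the
    oldest age sits in the final bin.  Returns (profiles, constant_features):
    features whose bin means do not vary are excluded from the profile matrix
    and listed separately.
    """
    ages = samples.ages(norm_log.columns)
    edges = np.asarray(edges, float)
    if (ages < edges[0]).any() or (ages > edges[-1]).any():
        bad = norm_log.columns[(ages < edges[0]) | (ages > edges[-1])][0]
        raise ValueError(f"sample {bad!r} falls outside the age bins")
    idx = np.searchsorted(edges, ages, side="right") - 1
    idx = np.minimum(idx, len(edges) - 2)  # close the last bin
    n_bins = len(edges) - 1
    counts_per_bin = np.bincount(idx, minlength=n_bins)
    if (counts_per_bin == 0).any():
        empty = [bin_labels(edges)[b] for b in np.flatnonzero(counts_per_bin == 0)]
        raise ValueError(f"empty age bin(s): {empty}")

    x = norm_log.to_numpy(float)
    means = np.column_stack([x[:, idx == b].mean(axis=1) for b in range(n_bins)])
    sd = means.std(axis=1, ddof=0)
    constant = sd == 0
    z = np.full_like(means, np.nan)
    nz = ~constant
    z[nz] = (means[nz] - means[nz].mean(axis=1, keepdims=True)) / sd[nz, None]
    profiles = pd.DataFrame(z[nz], index=norm_log.index[nz],
                            columns=bin_labels(edges))
    const_feats = list(norm_log.index[constant])
    if const_feats:
        logger.info("bin_mean_zscores: %d constant feature(s) excluded",
                    len(const_feats))
    return profiles, const_feats


@dataclass
class ClusterAssignment:
    """Per-feature cluster labels (0 = unassigned) and per-cluster summaries."""

    labels: pd.Series                 # feature -> cluster id (int; 0 unassigned)
    mean_profiles: pd.DataFrame       # cluster id x bins
    sizes: pd.Series                  # cluster id -> member count

    @property
    def unassigned(self) -> list[str]:
        return list(self.labels.index[self.labels == UNASSIGNED])

    def members(self, cluster_id: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster_id])


def cluster_zprofiles(profiles: pd.DataFrame, min_size: int = 15,
                      cut_height: float = 0.25) -> ClusterAssignment:
    """Average-linkage clustering of z-profiles under correlation distance.

    The dendrogram is cut at ``cut_height`` (d = 1 - Pearson r between
    profiles); clusters smaller than ``min_size`` are dissolved and their
    members marked unassigned.  Clusters are renumbered 1..K by descending
    size (ties by their lexicographically smallest member for determinism).
    """
    if profiles.shape[0] < min_size:
        raise ValueError(f"need at least min_size={min_size} features, "
                         f"got {profiles.shape[0]}")
    # deterministic input order regardless of caller's feature order
    profiles = profiles.sort_index(kind="stable")
    x = profiles.to_numpy(float)
    if not np.isfinite(x).all():
        raise ValueError("profiles contain non-finite values")
    # correlation distance; identical profiles meet at exactly 0
    d = ssd.pdist(x, metric="correlation")
    d = np.clip(d, 0.0, 2.0)
    link = sch.linkage(d, method="average")
    raw = sch.fcluster(link, t=cut_height, criterion="distance")

    labels = pd.Series(UNASSIGNED, index=profiles.index, dtype=int)
    groups = []
    for cid in np.unique(raw):
        members = profiles.index[raw == cid]
        if len(members) >= min_size:
            groups.append((len(members), str(members.min()), members))
    groups.sort(key=lambda t: (-t[0], t[1]))
    mean_rows, sizes = {}, {}
    for new_id, (size, _, members) in enumerate(groups, start=1):
        labels.loc[members] = new_id
        mean_rows[new_id] = profiles.loc[members].mean(axis=0)
        sizes[new_id] = size
    n_unassigned = int((labels == UNASSIGNED).sum())
    if n_unassigned:
        logger.info("cluster_zprofiles: %d feature(s) unassigned "
                    "(cluster < %d members)", n_unassigned, min_size)
    mean_profiles = (pd.DataFrame(mean_rows).T if mean_rows
                     else pd.DataFrame(columns=profiles.columns))
    return ClusterAssignment(labels=labels, mean_profiles=mean_profiles,
                             sizes=pd.Series(sizes, dtype=int))
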