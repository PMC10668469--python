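"""Core containers shared by every pipeline stage.

Counts, annotations and per-feature statistics all live in pandas objects;
these thin dataclasses add the invariants the pipeline relies on (unique
identifiers, non-negative integer counts, annotated subtypes) and fail fast
with located errors when an input violates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SMALL_RNA_SUBTYPES = ("miRNA", "piRNA", "circRNA", "snoRNA", "snRNA", "tRNA")
VALID_SUBTYPES = SMALL_RNA_SUBTYPES + ("mRNA", "other")


def _check_unique(values, what: str) -> None:
    s = pd.Series(values)
    dup = s[s.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate {what} identifier: {dup.iloc[0]!r}")


@dataclass
class CountMatrix:
    """Feature-by-sample matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame indexed by feature id with sample ids as columns.
    annotations
        DataFrame indexed by feature id with columns ``subtype`` (one of
        miRNA/piRNA/circRNA/snoRNA/snRNA/tRNA/mRNA/other) and
        ``uniquely_mapped`` (bool).  Missing columns are filled with the
        defaults ``other`` / ``True``.
    """

    counts: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "feature")
        _check_unique(self.counts.columns, "sample")
        arr = self.counts.to_numpy()
        if arr.size:
            bad = ~np.isfinite(arr.astype(float)) | (arr.astype(float) < 0) \
                | (arr.astype(float) != np.floor(arr.astype(float)))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"invalid count at (feature {self.counts.index[i]!r}, "
                    f"sample {self.counts.columns[j]!r}): "
                    f"{self.counts.iat[i, j]!r} (must be a non-negative integer)"
                )
        self.counts = self.counts.astype(np.int64)
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=self.counts.index)
        ann = self.annotations.reindex(self.counts.index)
        if "subtype" not in ann.columns:
            ann["subtype"] = "other"
        if "uniquely_mapped" not in ann.columns:
            ann["uniquely_mapped"] = True
        ann["subtype"] = ann["subtype"].fillna("other")
        ann["uniquely_mapped"] = ann["uniquely_mapped"].fillna(True).astype(bool)
        unknown = set(ann["subtype"]) - set(VALID_SUBTYPES)
        if unknown:
            raise ValueError(f"unknown subtype(s): {sorted(unknown)}")
        self.annotations = ann

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_features(self, feature_ids) -> "CountMatrix":
        feature_ids = list(feature_ids)
        return CountMatrix(self.counts.loc[feature_ids],
                           self.annotations.loc[feature_ids])

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.annotations)


@dataclass
class SampleTable:
    """Per-sample metadata: gestational age (weeks), sex, batch, layers."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        if "gestational_age" not in self.table.columns:
            raise ValueError("sample table requires a 'gestational_age' column")
        age = self.table["gestational_age"].astype(float)
        if not np.isfinite(age).all():
            bad = self.table.index[~np.isfinite(age)][0]
            raise ValueError(f"non-finite gestational age for sample {bad!r}")
        self.table = self.table.copy()
        self.table["gestational_age"] = age
        if "sex" not in self.table.columns:
            self.table["sex"] = "unknown"
        if "batch" not in self.table.columns:
            self.table["batch"] = "1"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def ages(self, sample_ids=None) -> np.ndarray:
        t = self.table if sample_ids is None else self.table.loc[list(sample_ids)]
        return t["gestational_age"].to_numpy(float)

    def require_samples(self, sample_ids) -> None:
        missing = set(sample_ids) - set(self.table.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")


@dataclass
class GeneSetCollection:
    """Ordered mapping set_id -> (description, member gene ids)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class TargetMap:
    """Predicted miRNA -> mRNA regulatory edges (deduplicated)."""

    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        for m, g in self.edges:
            if not m or not g:
                raise ValueError(f"target-map edge with empty identifier: {(m, g)!r}")

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.edges
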