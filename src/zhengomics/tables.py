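"""Feature-by-sample measurement tables with group metadata.

The central container is :class:`OmicsTable`: a features x samples matrix of
positive intensities (proteomics) or peak areas / concentrations
(metabolomics), a group label per sample, and a standard-sample flag used
for technical QC.  Standard samples carry the reserved group label ``STD``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

STANDARD_GROUP = "STD"


@dataclass
class OmicsTable:
    """Features x samples matrix plus per-sample group labels.

    Parameters
    ----------
    values
        DataFrame with feature ids as index and sample ids as columns.
        Entries are positive where present; missing values are NaN.
    groups
        Series mapping sample id -> group label (e.g. CCQS, QSBS, HC, STD).
    feature_meta
        Optional per-feature annotations (e.g. metabolite category),
        indexed by feature id.
    """

    values: pd.DataFrame
    groups: pd.Series
    feature_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without a group label: {missing[:5]}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() <= 0).any():
                raise ValueError("intensities must be positive where present")

    # -- basic accessors ---------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def standard_samples(self) -> list[str]:
        return self.samples_in_group(STANDARD_GROUP)

    def subset_groups(self, groups: list[str]) -> "OmicsTable":
        keep = [s for s in self.sample_ids if self.groups[s] in groups]
        return OmicsTable(self.values[keep], self.groups[keep], self.feature_meta)

    def has_missing(self) -> bool:
        return bool(self.values.isna().any().any())

    # -- serialization -----------------------------------------------------
    def to_tsv(self, matrix_path: str | Path, meta_path: str | Path) -> None:
        """Write the matrix (feature rows, sample columns) and sample metadata."""
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(matrix_path, sep="\t")
        meta = pd.DataFrame({"sample_id": self.groups.index, "group": self.groups.values})
        meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, meta_path: str | Path) -> "OmicsTable":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t")
        groups = pd.Series(meta["group"].values, index=meta["sample_id"].astype(str))
        values.columns = values.columns.astype(str)
        return cls(values, groups)
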