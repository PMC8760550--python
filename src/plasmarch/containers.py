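"""In-memory containers shared across pipeline stages.

The central object is :class:`MFIMatrix`, a samples x antibodies matrix of
positive median fluorescence intensities (MFI) together with the plate
assignment of every sample and, optionally, the sample roles (study /
replicate / double / pool). All normalization, QC and clustering stages
consume and return this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ROLES = ("study", "replicate", "double", "pool")


class MFIMatrix:
    """Positive samples x antibodies intensity matrix with plate map.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, one column per antibody id.
        All entries must be finite and strictly positive (MFI units).
    plates
        Mapping or Series sample id -> plate id; every sample must be
        assigned to a plate.
    roles
        Optional mapping sample id -> role in ``{"study", "replicate",
        "double", "pool"}``. Stages that need to exclude pools or
        replicates consult this; when absent every sample is treated as
        a study sample.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        plates: Mapping[str, str] | pd.Series,
        roles: Mapping[str, str] | pd.Series | None = None,
    ):
        values = pd.DataFrame(values).astype(float)
        if values.index.has_duplicates:
            raise ValueError("duplicated sample ids")
        if values.columns.has_duplicates:
            raise ValueError("duplicated antibody ids")
        arr = values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("MFI values must be finite")
        if np.any(arr <= 0):
            raise ValueError("MFI values must be strictly positive")
        plates = pd.Series(plates)
        missing = values.index.difference(plates.index)
        if len(missing):
            raise ValueError(f"samples without plate assignment: {list(missing)[:5]}")
        self.values = values
        self.plates = plates.reindex(values.index).astype(str)
        if roles is None:
            self.roles = pd.Series("study", index=values.index)
        else:
            roles = pd.Series(roles).reindex(values.index)
            if roles.isna().any():
                raise ValueError("samples without role assignment")
            bad = set(roles.unique()) - set(ROLES)
            if bad:
                raise ValueError(f"unknown roles: {sorted(bad)}")
            self.roles = roles.astype(str)

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def antibody_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def log(self) -> pd.DataFrame:
        """Natural-log intensities as a DataFrame."""
        return np.log(self.values)

    def subset(
        self,
        samples: Iterable[str] | None = None,
        antibodies: Iterable[str] | None = None,
    ) -> "MFIMatrix":
        v = self.values
        if samples is not None:
            v = v.loc[list(samples)]
        if antibodies is not None:
            v = v[list(antibodies)]
        return MFIMatrix(v, self.plates, self.roles)

    def with_values(self, values: pd.DataFrame) -> "MFIMatrix":
        """Same metadata, new value matrix (same index/columns)."""
        return MFIMatrix(values, self.plates, self.roles)

    def copy(self) -> "MFIMatrix":
        return MFIMatrix(self.values.copy(), self.plates, self.roles)

    def __repr__(self) -> str:  # pragma: no cover
        n, p = self.shape
        return f"MFIMatrix({n} samples x {p} antibodies, {self.plates.nunique()} plates)"


@dataclass
class QCReport:
    """Per-antibody QC statistics and exclusion flags.

    ``antibody`` rows carry the replicate Spearman rho, the IgG Spearman
    rho, the empty-well MFI and the study-sample mean/sd that enter the
    background rule, plus one boolean column per flag. ``samples`` maps
    sample id -> exclusion reason (or absent if kept).
    """

    antibody: pd.DataFrame
    samples: pd.Series
    thresholds: dict = field(default_factory=dict)

    def flagged(self) -> pd.Index:
        flag_cols = [c for c in self.antibody.columns if c.startswith("flag_")]
        mask = self.antibody[flag_cols].any(axis=1)
        return self.antibody.index[mask]


@dataclass
class DifferentialResult:
    """Cluster-vs-rest differential abundance table.

    One row per antibody: mean log-MFI difference (cluster minus rest),
    Welch t statistic, two-sided p, BH FDR, signed linear-scale median
    fold change and the direction of change.
    """

    table: pd.DataFrame
    cluster_id: int
    n_cluster: int
    n_rest: int
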