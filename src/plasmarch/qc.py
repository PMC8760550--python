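"""Antibody quality control and filtering.

Three exclusion criteria are applied per antibody:

* low reproducibility: Spearman rho across duplicated (replicate)
  samples below ``rho_rep`` (default 0.7);
* IgG correlation: Spearman rho against per-sample IgG levels above
  ``rho_igg`` (default 0.5), catching antibodies that read out bulk
  immunoglobulin rather than their target;
* elevated background: empty-well buffer MFI above
  mean + ``bg_sd`` x sd of the study-sample MFI (default 3 sd).

Surviving antibodies sharing a target gene are de-duplicated, keeping
the one with the highest replicate correlation (ties broken by
antibody id). Replicate samples are dropped from the matrix before
analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import MFIMatrix, QCReport

__all__ = ["compute_qc", "apply_qc", "replicate_pairs_from_samples"]

DEFAULT_THRESHOLDS = {"rho_rep": 0.7, "rho_igg": 0.5, "bg_sd": 3.0}


def replicate_pairs_from_samples(samples: pd.DataFrame) -> list[tuple[str, str]]:
    """Replicate sample-id pairs from an annotation table (role == replicate,
    paired by subject_id)."""
    rep = samples[samples["role"] == "replicate"]
    pairs = []
    for _, grp in rep.groupby("subject_id"):
        ids = list(grp.index)
        for a, b in zip(ids[::2], ids[1::2]):
            pairs.append((a, b))
    return pairs


def _spearman_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise Spearman rho between matrices with matching shapes
    (or y a vector broadcast against all columns of x)."""
    rx = rankdata(x, axis=0)
    rx = rx - rx.mean(axis=0)
    nx = np.sqrt((rx ** 2).sum(axis=0))
    nx[nx == 0] = np.nan
    if y.ndim == 1:
        ry = rankdata(y)
        ry = ry - ry.mean()
        ny = np.sqrt((ry ** 2).sum())
        return (rx.T @ ry) / (nx * (ny if ny else np.nan))
    ry = rankdata(y, axis=0)
    ry = ry - ry.mean(axis=0)
    ny = np.sqrt((ry ** 2).sum(axis=0))
    ny[ny == 0] = np.nan
    return (rx * ry).sum(axis=0) / (nx * ny)


def compute_qc(
    matrix: MFIMatrix,
    replicate_pairs: list[tuple[str, str]],
    igg_profile: pd.Series,
    empty_profile: pd.Series,
    thresholds: dict | None = None,
) -> QCReport:
    """Per-antibody QC statistics and flags.

    ``replicate_pairs`` are (first, second) sample-id tuples of duplicated
    assays; ``igg_profile`` is the per-sample IgG level; ``empty_profile``
    the per-antibody empty-well buffer MFI.
    """
    th = dict(DEFAULT_THRESHOLDS)
    th.update(thresholds or {})
    if len(replicate_pairs) < 3:
        raise ValueError("need at least 3 replicate pairs")
    ab = matrix.values.columns
    if not ab.equals(pd.Index(empty_profile.index)):
        raise ValueError("empty-well profile antibody ids misaligned with matrix")

    first = matrix.values.loc[[a for a, _ in replicate_pairs]].to_numpy()
    second = matrix.values.loc[[b for _, b in replicate_pairs]].to_numpy()
    rep_rho = _spearman_columns(first, second)

    study_ids = matrix.values.index[(matrix.roles == "study").to_numpy()]
    if len(study_ids) == 0:
        study_ids = matrix.values.index
    igg = igg_profile.reindex(study_ids)
    if igg.isna().any():
        raise ValueError("IgG profile missing study samples")
    study = matrix.values.loc[study_ids].to_numpy()
    igg_rho = _spearman_columns(study, igg.to_numpy())

    smean = study.mean(axis=0)
    ssd = study.std(axis=0, ddof=1)
    empty = empty_profile.to_numpy(float)

    table = pd.DataFrame(
        {
            "replicate_rho": rep_rho,
            "igg_rho": igg_rho,
            "empty_mfi": empty,
            "sample_mean_mfi": smean,
            "sample_sd_mfi": ssd,
        },
        index=ab,
    )
    table["flag_low_reproducibility"] = table["replicate_rho"] < th["rho_rep"]
    table["flag_igg_correlated"] = table["igg_rho"] > th["rho_igg"]
    table["flag_high_background"] = table["empty_mfi"] > (
        table["sample_mean_mfi"] + th["bg_sd"] * table["sample_sd_mfi"])

    sample_excl = pd.Series(
        "replicate", index=matrix.values.index[(matrix.roles == "replicate").to_numpy()]
    )
    return QCReport(antibody=table, samples=sample_excl, thresholds=th)


def apply_qc(
    matrix: MFIMatrix,
    report: QCReport,
    antibody_table: pd.DataFrame | None = None,
    drop_roles: tuple[str, ...] = ("replicate", "pool"),
) -> MFIMatrix:
    """Drop flagged antibodies, de-duplicate shared targets, prune samples.

    Among surviving antibodies with the same target gene exactly one is
    kept: highest replicate rho, ties by antibody id. Samples whose role
    is in ``drop_roles`` are removed. Raises if no antibody survives.
    """
    if not report.antibody.index.equals(matrix.values.columns):
        raise ValueError("QC report antibody ids do not match matrix")
    keep = report.antibody.index.difference(report.flagged(), sort=False)
    if antibody_table is not None:
        targets = antibody_table.loc[keep, "target_gene"]
        ranked = pd.DataFrame({
            "antibody": keep,
            "target": targets.to_numpy(),
            "rho": report.antibody.loc[keep, "replicate_rho"].to_numpy(),
        })
        # within target: best replicate rho first, ties by antibody id
        ranked = ranked.sort_values(["target", "rho", "antibody"],
                                    ascending=[True, False, True])
        winners = set(ranked.groupby("target").head(1)["antibody"])
        keep = pd.Index([a for a in matrix.values.columns if a in winners])
    if len(keep) == 0:
        raise ValueError("no antibodies survive QC")
    rows = matrix.values.index[~matrix.roles.isin(drop_roles).to_numpy()]
    return matrix.subset(samples=rows, antibodies=keep)
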