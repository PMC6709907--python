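"""ΔCt relative quantification.

Raw qPCR cycle-threshold (Ct) values for a target gene are normalized to a
reference gene (here typically beta-2 microglobulin, B2M) per sample:
``rq = E^-(Ct_target - Ct_ref)`` with amplification efficiency E fixed at 2,
the classic ΔCt convention.  Technical replicates are averaged on the Ct
scale.  The resulting relative quantities are positive and unitless and feed
the lognormal GLM as continuous records; group comparison happens there, so
no ΔΔCt calibrator sample is used.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import MeasurementTable, RecordError, SchemaError

__all__ = [
    "average_technical_replicates",
    "delta_ct_relative_quantity",
    "build_rq_table",
    "load_ct_table",
]

CT_COLUMNS = ("sample_id", "gene", "ct")


def average_technical_replicates(cts) -> float:
    """Arithmetic mean of technical-replicate Cts for one sample × gene."""
    arr = np.asarray(list(cts), dtype=float)
    if arr.size == 0:
        raise ValueError("no Ct observations to average")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite Ct value (non-detects are not accepted)")
    return float(arr.mean())


def delta_ct_relative_quantity(ct_target: float, ct_ref: float, efficiency: float = 2.0) -> float:
    """Relative quantity ``efficiency ** -(ct_target - ct_ref)``.

    Strictly decreasing in ``ct_target`` and increasing in ``ct_ref``;
    always positive.
    """
    if not (np.isfinite(ct_target) and np.isfinite(ct_ref)):
        raise ValueError("Ct values must be finite")
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    return float(efficiency ** -(float(ct_target) - float(ct_ref)))


def load_ct_table(path) -> pd.DataFrame:
    """Read a Ct file (columns sample_id, gene, ct[, replicate, batch])."""
    df = pd.read_csv(path)
    for col in CT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    return df


def build_rq_table(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    sample_annotations: pd.DataFrame,
    efficiency: float = 2.0,
    metadata: dict | None = None,
) -> MeasurementTable:
    """ΔCt-normalize a Ct table into a continuous MeasurementTable.

    Parameters
    ----------
    ct_table : DataFrame
        Columns ``sample_id``, ``gene``, ``ct`` and optionally ``replicate``
        and ``batch``.  Technical replicates are averaged on the Ct scale.
    target_gene, reference_gene : str
        Gene names; every sample must carry both after averaging.
    sample_annotations : DataFrame
        One row per ``sample_id`` with at least ``genotype`` and one grouping
        column (``litter``, ``animal`` or ``batch``).
    """
    for col in CT_COLUMNS:
        if col not in ct_table.columns:
            raise SchemaError(f"missing required column {col!r}")
    if "sample_id" not in sample_annotations.columns:
        raise SchemaError("sample_annotations needs a 'sample_id' column")
    ann = sample_annotations.set_index("sample_id")

    sub = ct_table[ct_table["gene"].isin([target_gene, reference_gene])]
    means = (
        sub.groupby(["sample_id", "gene"], sort=False)["ct"]
        .apply(average_technical_replicates)
        .unstack("gene")
    )
    rows = []
    for sample_id in ct_table["sample_id"].drop_duplicates():
        if sample_id not in means.index or pd.isna(means.at[sample_id, target_gene] if target_gene in means.columns else np.nan):
            raise RecordError(f"sample {sample_id!r} is missing target gene {target_gene!r}")
        if reference_gene not in means.columns or pd.isna(means.at[sample_id, reference_gene]):
            raise RecordError(f"sample {sample_id!r} is missing reference gene {reference_gene!r}")
        rq = delta_ct_relative_quantity(
            means.at[sample_id, target_gene], means.at[sample_id, reference_gene], efficiency
        )
        if sample_id not in ann.index:
            raise RecordError(f"sample {sample_id!r} has no annotations")
        row = {"value": rq, "animal": sample_id}
        row.update(ann.loc[sample_id].dropna().to_dict())
        rows.append(row)

    meta = {"units": "relative quantity", "reference_gene": reference_gene, "target_gene": target_gene}
    meta.update(metadata or {})
    return MeasurementTable(pd.DataFrame(rows), kind="continuous", metadata=meta)
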