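"""Relative expression from qPCR Ct tables by the 2^-ddCt method.

For each well, dCt = Ct_target - Ct_reference (the reference gene, e.g.
maize Actin 1, paired by condition and replicate).  ddCt subtracts the
calibrator condition's mean dCt for the same gene, and the fold change is
2^-ddCt, so the calibrator normalizes to 1 when replicate noise is zero.

Replicates are treated as exchangeable by default; the table carries a
``replicate_type`` column (technical/biological) so either kind can be
pooled or selected.  The standard error is computed on per-replicate fold
values, matching the fold-scale error bars of typical expression figures; a
log-scale (ddCt-scale) SE is also reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("gene", "condition", "replicate", "ct")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if not np.isfinite(table["ct"]).all() or (table["ct"] <= 0).any():
        bad = table.loc[~np.isfinite(table["ct"]) | (table["ct"] <= 0)]
        raise ValueError(f"non-finite or non-positive Ct values:\n{bad}")
    return table


def delta_delta_ct(
    table: pd.DataFrame,
    reference_gene: str = "Actin1",
    calibrator: str = "CK",
    replicate_type: str | None = None,
) -> pd.DataFrame:
    """Per gene x condition relative expression 2^-ddCt.

    Returns a DataFrame with columns gene, condition, n_replicates,
    delta_ct_mean, delta_delta_ct_mean, fold, se, se_log.  ``fold`` is the
    mean of per-replicate 2^-ddCt values; ``se`` their standard error;
    ``se_log`` the standard error of the per-replicate ddCt values.

    Raises when the reference gene misses a (condition, replicate) that a
    target was measured in, or when a gene lacks the calibrator condition.
    """
    table = _validate(table)
    if replicate_type is not None:
        if "replicate_type" not in table.columns:
            raise ValueError("table has no replicate_type column")
        table = table[table["replicate_type"] == replicate_type]

    ref = table[table["gene"] == reference_gene]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    ref_ct = ref.set_index(["condition", "replicate"])["ct"]
    if ref_ct.index.has_duplicates:
        ref_ct = ref_ct.groupby(level=[0, 1]).mean()

    targets = table[table["gene"] != reference_gene].copy()
    missing = [
        key
        for key in targets[["condition", "replicate"]].drop_duplicates().itertuples(index=False)
        if (key.condition, key.replicate) not in ref_ct.index
    ]
    if missing:
        raise ValueError(
            f"reference gene {reference_gene!r} not measured in samples: "
            f"{[(m.condition, m.replicate) for m in missing]}"
        )
    targets["delta_ct"] = targets["ct"].to_numpy() - ref_ct.loc[
        list(targets[["condition", "replicate"]].itertuples(index=False, name=None))
    ].to_numpy()

    rows = []
    for gene, sub in targets.groupby("gene", sort=False):
        cal = sub[sub["condition"] == calibrator]
        if cal.empty:
            raise ValueError(f"calibrator {calibrator!r} missing for gene {gene!r}")
        cal_mean = cal["delta_ct"].mean()
        for cond, cs in sub.groupby("condition", sort=False):
            ddct = cs["delta_ct"].to_numpy() - cal_mean
            folds = np.exp2(-ddct)
            n = len(folds)
            se = folds.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
            se_log = ddct.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
            rows.append(
                (gene, cond, n, cs["delta_ct"].mean(), ddct.mean(), folds.mean(), se, se_log)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "condition",
            "n_replicates",
            "delta_ct_mean",
            "delta_delta_ct_mean",
            "fold",
            "se",
            "se_log",
        ],
    )


def tissue_profile(
    table: pd.DataFrame,
    reference_gene: str = "Actin1",
    baseline_tissue: str = "leaf",
    replicate_type: str | None = None,
) -> pd.DataFrame:
    """Tissue expression profile: the 2^-ddCt computation with a baseline
    tissue (e.g. leaf) as the calibrator condition."""
    return delta_delta_ct(
        table,
        reference_gene=reference_gene,
        calibrator=baseline_tissue,
        replicate_type=replicate_type,
    )
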