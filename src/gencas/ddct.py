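"""ddCt relative quantification of qPCR cycle-threshold tables.

For each replicate, dCt = Ct(target) - mean Ct(reference genes); for each
gene and condition, ddCt = mean dCt(condition) - mean dCt(reference
condition) and the fold change is 2^-ddCt (amplification efficiency fixed at
2).  The standard deviation of ddCt is the root of the summed replicate
variances of the two dCt means, mapped through the exponential at first
order: sd(fold) = ln2 * fold * sd(ddCt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

CT_COLUMNS = ("gene", "condition", "replicate", "ct", "is_reference")


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    condition: str
    fold_change: float
    sd: float | None  # None when only one replicate
    reference_condition: str


def _validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    table = table.copy()
    table["ct"] = table["ct"].astype(float)
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    table["is_reference"] = table["is_reference"].astype(bool)
    return table


def ddct_fold_changes(
    table: pd.DataFrame, reference_condition: str = "glucose"
) -> list[FoldChangeResult]:
    """2^-ddCt fold changes per gene and condition, relative to the
    reference condition, normalised to the mean of the reference genes.

    Multiple reference genes are combined by the arithmetic mean of their
    Cts within each replicate.  Every replicate of every condition must
    include at least one reference-gene measurement.
    """
    table = _validate_ct_table(table)
    if reference_condition not in set(table["condition"]):
        raise ValueError(f"reference condition {reference_condition!r} not in table")

    # per-replicate mean reference Ct
    refs = table[table["is_reference"]]
    for cond, sub in table.groupby("condition"):
        if not sub["is_reference"].any():
            raise ValueError(f"no reference gene measured in condition {cond!r}")
    ref_ct = (
        refs.groupby(["condition", "replicate"])["ct"].mean().rename("ref_ct").reset_index()
    )
    merged = table.merge(ref_ct, on=["condition", "replicate"], how="left")
    if merged["ref_ct"].isna().any():
        bad = merged[merged["ref_ct"].isna()][["condition", "replicate"]].iloc[0]
        raise ValueError(
            f"no reference gene in condition {bad['condition']!r}, replicate {bad['replicate']!r}"
        )
    merged["dct"] = merged["ct"] - merged["ref_ct"]

    stats = (
        merged.groupby(["gene", "condition"])["dct"]
        .agg(mean="mean", var="var", n="count")  # var is ddof=1, NaN for n=1
        .reset_index()
    )
    base = stats[stats["condition"] == reference_condition].set_index("gene")

    results = []
    for row in stats.itertuples(index=False):
        if row.gene not in base.index:
            raise ValueError(
                f"gene {row.gene!r} not measured in reference condition {reference_condition!r}"
            )
        b = base.loc[row.gene]
        ddct = row.mean - b["mean"]
        fold = 2.0 ** (-ddct)
        if row.n > 1 and b["n"] > 1:
            sd_ddct = math.sqrt(row.var / 1.0 + b["var"] / 1.0)
            sd: float | None = math.log(2.0) * fold * sd_ddct
        else:
            sd = None
        results.append(
            FoldChangeResult(
                gene=str(row.gene),
                condition=str(row.condition),
                fold_change=float(fold),
                sd=sd,
                reference_condition=reference_condition,
            )
        )
    results.sort(key=lambda r: (r.gene, r.condition))
    return results


def fold_changes_to_frame(results: list[FoldChangeResult]) -> pd.DataFrame:
    rows = [
        {
            "gene": r.gene,
            "condition": r.condition,
            "fold_change": r.fold_change,
            "sd": r.sd if r.sd is not None else "",
            "reference_condition": r.reference_condition,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["gene", "condition", "fold_change", "sd", "reference_condition"]
    )
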