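"""Proportional cone-opsin expression from mapped-read counts.

Damselfish single cones express the SWS genes (SWS1 copies and SWS2B) and
double cones the RH2A/RH2B/LWS genes, so proportions are computed within
each cone class separately: for gene i, N_i = mapped reads / CDS length and
the proportion is N_i / sum of N_j over the genes of the same cone class.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import pandas as pd

SINGLE_CONE = "single-cone"
DOUBLE_CONE = "double-cone"

#: default cone-class membership; gene names are normalized (upper-case,
#: Greek suffixes mapped to latin a/b) before lookup
DEFAULT_GENE_GROUPS: dict[str, str] = {
    "SWS1": SINGLE_CONE,
    "SWS1A": SINGLE_CONE,
    "SWS1B": SINGLE_CONE,
    "SWS2B": SINGLE_CONE,
    "RH2A": DOUBLE_CONE,
    "RH2B": DOUBLE_CONE,
    "LWS": DOUBLE_CONE,
}

USAGE_BOTH = "both copies"
USAGE_ONE = "one copy"
USAGE_NONE = "none"


class ExpressionError(ValueError):
    pass


def normalize_gene(name: str) -> str:
    return name.replace("α", "a").replace("β", "b").strip().upper()


def proportional_expression(
    table: pd.DataFrame, gene_groups: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Length-normalized within-group expression proportions.

    ``table`` needs columns sample, gene, mapped_reads, cds_length. Returns a
    frame with columns sample, gene, group, proportion; proportions sum to 1
    per (sample, group) wherever the group has any reads, and are NaN
    (undefined, not zero) for groups with no reads at all.
    """
    groups = DEFAULT_GENE_GROUPS if gene_groups is None else gene_groups
    required = {"sample", "gene", "mapped_reads", "cds_length"}
    if not required.issubset(table.columns):
        raise ExpressionError(f"count table must have columns {sorted(required)}")

    df = table.copy()
    df["gene"] = df["gene"].map(normalize_gene)
    if (df["mapped_reads"] < 0).any():
        raise ExpressionError("negative mapped_reads")
    if (df["cds_length"] <= 0).any() or df["cds_length"].isna().any():
        bad = df.loc[(df["cds_length"] <= 0) | df["cds_length"].isna(), "gene"].tolist()
        raise ExpressionError(f"non-positive or missing CDS length for {bad}")
    unknown = sorted(set(df["gene"]) - set(groups))
    if unknown:
        raise ExpressionError(f"genes without a cone-class assignment: {unknown}")

    df["group"] = df["gene"].map(groups)
    df["rate"] = df["mapped_reads"] / df["cds_length"]
    totals = df.groupby(["sample", "group"])["rate"].transform("sum")
    df["proportion"] = df["rate"].where(totals > 0) / totals.where(totals > 0)
    return df[["sample", "gene", "group", "proportion"]].reset_index(drop=True)


def classify_sws1_usage(
    proportions: pd.DataFrame,
    sws1_genes: Iterable[str] | None = None,
    detection_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-sample SWS1 copy usage: both copies / one copy / none.

    A paralogue counts as expressed when its single-cone proportion is
    strictly above ``detection_threshold``. By default every gene whose
    normalized name starts with SWS1 is treated as an SWS1 paralogue.
    """
    rows = []
    for sample, sub in proportions.groupby("sample"):
        if sws1_genes is None:
            paralogues = [g for g in sub["gene"].unique() if g.startswith("SWS1")]
        else:
            paralogues = [normalize_gene(g) for g in sws1_genes]
        sws1 = sub[sub["gene"].isin(paralogues)]
        if sws1.empty:
            warnings.warn(f"{sample}: no SWS1 gene in table")
            rows.append({"sample": sample, "n_expressed": 0, "usage": USAGE_NONE})
            continue
        n = int((sws1["proportion"] > detection_threshold).sum())
        usage = USAGE_BOTH if n >= 2 else (USAGE_ONE if n == 1 else USAGE_NONE)
        rows.append({"sample": sample, "n_expressed": n, "usage": usage})
    out = pd.DataFrame(rows)
    out.attrs["detection_threshold"] = detection_threshold
    return out
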