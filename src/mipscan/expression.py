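"""FPKM expression thresholding and per-plant summaries.

Transcript abundances below 1 FPKM are treated as no expression; exactly 1 is
expressed.  Organ columns may carry multiple conditions ("root.drought",
"root.control"): a gene counts as expressed in an organ if any condition
reaches the threshold.
"""

from __future__ import annotations

import pandas as pd

FPKM_THRESHOLD = 1.0


def read_fpkm(path) -> pd.DataFrame:
    """Gene x organ/condition FPKM matrix from TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _validate(df)
    return df


def _validate(matrix: pd.DataFrame) -> None:
    if matrix.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    if (matrix.values < 0).any():
        raise ValueError("negative FPKM values")


def flag_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Boolean matrix: entry true iff FPKM >= 1 (FPKM < 1 is no expression)."""
    _validate(matrix)
    return matrix >= FPKM_THRESHOLD


def collapse_conditions(flags: pd.DataFrame) -> pd.DataFrame:
    """Aggregate condition columns to organs (``organ.condition`` -> ``organ``).

    A gene is expressed in an organ if any of the organ's conditions is
    expressed.
    """
    organs = [str(c).split(".", 1)[0] for c in flags.columns]
    return flags.T.groupby(organs).any().T


def summarize_expression(
    flags: pd.DataFrame,
    plant_grouping,
    *,
    rounded: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-plant expression percentages plus per-gene maxima of the flags input.

    ``plant_grouping`` maps gene id -> plant label (dict or callable).
    Returns (summary, per-gene expressed-organ counts).  The summary has, per
    plant, the percentage of genes expressed in at least one organ and in all
    organs; percentages are rounded to integers unless ``rounded=False``.
    """
    organ_flags = collapse_conditions(flags)
    if callable(plant_grouping):
        plants = organ_flags.index.map(plant_grouping)
    else:
        plants = organ_flags.index.map(lambda g: plant_grouping[g])
    any_organ = organ_flags.any(axis=1)
    all_organs = organ_flags.all(axis=1)
    records = []
    for plant in pd.unique(plants):
        mask = plants == plant
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"empty plant group {plant!r}")
        pct_any = 100.0 * any_organ[mask].sum() / n
        pct_all = 100.0 * all_organs[mask].sum() / n
        if rounded:
            pct_any, pct_all = round(pct_any), round(pct_all)
        records.append(
            {
                "plant": plant,
                "n_genes": n,
                "pct_any_organ": pct_any,
                "pct_all_organs": pct_all,
            }
        )
    summary = pd.DataFrame.from_records(records).set_index("plant")
    return summary, organ_flags.sum(axis=1)


def max_fpkm(matrix: pd.DataFrame) -> pd.Series:
    """Per-gene maximum FPKM over all organs/conditions."""
    _validate(matrix)
    return matrix.max(axis=1)


def heatmap_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Heatmap-ready organ-collapsed FPKM values (max over conditions)."""
    _validate(matrix)
    organs = [str(c).split(".", 1)[0] for c in matrix.columns]
    return matrix.T.groupby(organs).max().T
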