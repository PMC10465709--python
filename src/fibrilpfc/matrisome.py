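"""Matrisome abundance time series: complete-case filtering, normalization to
E12.5 and log2 fold-change trajectories.

The five fixed time points span E12.5-E14.5, the window over which collagen
fibrils first appear in embryonic mouse tail tendon. Proteins missing a value
at any time point are excluded; the remaining abundances are divided by their
E12.5 value and log2-transformed, so soluble collagen-I chains show the
characteristic rise-to-E13.5-then-decline signature. No imputation and no
significance testing is performed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import TIMEPOINTS


def _check_columns(table: pd.DataFrame) -> None:
    if list(table.columns) != list(TIMEPOINTS):
        raise ValueError(
            f"expected columns {list(TIMEPOINTS)}, got {list(table.columns)}"
        )


def read_abundance_csv(path) -> pd.DataFrame:
    """Read a protein x time-point abundance CSV (empty cell = missing)."""
    table = pd.read_csv(path, index_col=0)
    table.columns = [str(c).strip() for c in table.columns]
    _check_columns(table)
    bad = table[(table <= 0).any(axis=1)].index
    if len(bad):
        raise ValueError(f"non-positive abundances for proteins: {', '.join(map(str, bad[:5]))}")
    return table


def write_abundance_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path)


def filter_complete(table: pd.DataFrame) -> pd.DataFrame:
    """Retain only proteins quantified at all five time points (order kept)."""
    _check_columns(table)
    return table.dropna(axis=0, how="any")


def log2_fold_change(table: pd.DataFrame) -> pd.DataFrame:
    """log2(a_t / a_E12.5) per protein; the E12.5 column is identically 0.

    Requires a complete-case table with positive E12.5 abundances.
    """
    _check_columns(table)
    if table.isna().any().any():
        raise ValueError("table has missing values; run filter_complete first")
    ref = table[TIMEPOINTS[0]]
    bad = ref.index[(ref <= 0) | ~np.isfinite(ref)]
    if len(bad):
        raise ValueError(
            "non-positive E12.5 reference abundance for: " + ", ".join(map(str, bad[:10]))
        )
    fc = np.log2(table.div(ref, axis=0))
    fc[TIMEPOINTS[0]] = 0.0
    return fc


def peak_timepoint(fc: pd.DataFrame) -> pd.Series:
    """Time point of maximal fold change per protein; ties -> earliest."""
    _check_columns(fc)
    if fc.isna().any().any():
        raise ValueError("fold-change table has missing values")
    return fc.idxmax(axis=1).rename("peak")


def annotate_categories(fc: pd.DataFrame, categories: pd.Series | None) -> pd.DataFrame:
    """Attach a matrisome category column (e.g. collagens, glycoproteins).

    ``categories`` maps protein ID -> category label; unannotated proteins
    get "unassigned".
    """
    out = fc.copy()
    if categories is None:
        out["category"] = "unassigned"
    else:
        out["category"] = categories.reindex(fc.index).fillna("unassigned")
    return out


def read_categories_csv(path) -> pd.Series:
    """Two-column CSV (protein, category) -> Series."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("categories CSV needs two columns: protein, category")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="category")


def to_long(fc: pd.DataFrame, categories: pd.Series | None = None) -> pd.DataFrame:
    """Heatmap-ready long format: (protein, timepoint, log2fc, category)."""
    ann = annotate_categories(fc, categories)
    long = (
        ann.reset_index()
        .melt(
            id_vars=[ann.index.name or "index", "category"],
            value_vars=list(TIMEPOINTS),
            var_name="timepoint",
            value_name="log2fc",
        )
        .rename(columns={ann.index.name or "index": "protein"})
    )
    return long[["protein", "timepoint", "log2fc", "category"]]


def fold_change_pipeline(
    table: pd.DataFrame, categories: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """filter_complete -> log2_fold_change -> peak_timepoint in one call."""
    complete = filter_complete(table)
    fc = log2_fold_change(complete)
    peaks = peak_timepoint(fc) if len(fc) else pd.Series(dtype=object, name="peak")
    return fc, peaks
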