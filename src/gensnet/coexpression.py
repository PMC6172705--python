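"""Per-edge expression correlations (the C_ij edge-weight coefficients).

The expression matrix is a pandas DataFrame (genes x samples).  Correlations
are Pearson over pairwise-complete samples; an edge whose correlation cannot
be computed (gene missing, fewer than 3 complete pairs, zero variance) gets
the sentinel ``None`` rather than an error — downstream weighting substitutes
a configurable default.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_SAMPLES = 3


def read_expression(path: str | Path, uppercase: bool = True) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene symbol).

    Duplicate gene rows are averaged (logged).  Cells that fail numeric
    parsing other than the usual NA spellings are reported with coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "na", ""])
    if df.shape[1] < MIN_SAMPLES:
        raise ValueError(
            f"{path}: {df.shape[1]} sample column(s), need at least {MIN_SAMPLES}"
        )
    df.index = df.index.astype(str).str.strip()
    if uppercase:
        df.index = df.index.str.upper()
    df.index.name = "gene"

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"{path}: non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if numeric.index.duplicated().any():
        n = int(numeric.index.duplicated().sum())
        logger.warning("%s: %d duplicate gene row(s) averaged", path, n)
        numeric = numeric.groupby(level=0, sort=False).mean()
    return numeric


def edge_correlation(expr: pd.DataFrame, gene_i: str, gene_j: str) -> float | None:
    """Pearson correlation of two genes over pairwise-complete samples.

    Returns ``None`` (ABSENT) when either gene is missing from the matrix,
    fewer than 3 complete sample pairs remain, or either vector is constant.
    """
    if gene_i not in expr.index or gene_j not in expr.index:
        return None
    if gene_j < gene_i:  # canonical order makes symmetry exact, not just to fp error
        gene_i, gene_j = gene_j, gene_i
    x = expr.loc[gene_i].to_numpy(dtype=float)
    y = expr.loc[gene_j].to_numpy(dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < MIN_SAMPLES:
        return None
    x, y = x[mask], y[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    # guard against tiny fp excursions outside [-1, 1]
    return max(-1.0, min(1.0, r))


def correlation_map(
    expr: pd.DataFrame, edges: Iterable[tuple[str, str]]
) -> dict[tuple[str, str], float | None]:
    """Correlations for many edges, keyed by the unordered (sorted) pair."""
    out: dict[tuple[str, str], float | None] = {}
    for a, b in edges:
        key = (a, b) if a < b else (b, a)
        if key not in out:
            out[key] = edge_correlation(expr, *key)
    return out


def write_edge_correlations(
    corr: dict[tuple[str, str], float | None], path: str | Path
) -> None:
    with Path(path).open("w") as handle:
        handle.write("gene_a\tgene_b\tcorrelation\n")
        for (a, b) in sorted(corr):
            c = corr[(a, b)]
            handle.write(f"{a}\t{b}\t{'NA' if c is None else format(c, '.10g')}\n")
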