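"""Gene-level association scores: loading, MHC exclusion, significance cuts.

Gene-level p-values (e.g. VEGAS output aggregating SNP associations per gene)
are kept in a pandas DataFrame indexed by gene symbol with columns ``chrom``,
``start``, ``end`` (1-based inclusive; may be missing) and ``p``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Extended-LD region excluded by default: the MHC on chromosome 6, 25-34 Mb.
MHC_CHROM = "6"
MHC_LO = 25_000_000
MHC_HI = 34_000_000

#: Floor applied to p-values of exactly 0 (the resolution of a 10^6-replicate
#: Monte-Carlo gene test).
DEFAULT_P_FLOOR = 1e-6


def _norm_chrom(label: object) -> str | None:
    if label is None or (isinstance(label, float) and np.isnan(label)):
        return None
    text = str(label).strip()
    if not text or text.lower() in ("nan", "na", "."):
        return None
    if text.lower().startswith("chr"):
        text = text[3:]
    return text


def read_gene_scores(
    path: str | Path,
    p_floor: float = DEFAULT_P_FLOOR,
    uppercase: bool = True,
) -> pd.DataFrame:
    """Read a gene-score TSV (columns gene, chrom, start, end, p).

    Coordinate columns are optional.  Rows with p outside (0, 1] are rejected
    with their row number; p of exactly 0 is clamped up to ``p_floor`` with a
    warning.  Duplicate genes keep the smallest p (logged).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    df.columns = [c.strip().lower() for c in df.columns]
    if "gene" not in df.columns or "p" not in df.columns:
        raise ValueError(f"{path}: required columns 'gene' and 'p' not found")
    df["gene"] = df["gene"].str.strip()
    if uppercase:
        df["gene"] = df["gene"].str.upper()
    df["p"] = pd.to_numeric(df["p"], errors="coerce")

    bad = df.index[df["p"].isna() | (df["p"] < 0) | (df["p"] > 1)]
    if len(bad):
        # +2: header line plus 1-based numbering
        rows = ", ".join(str(i + 2) for i in bad[:10])
        raise ValueError(f"{path}: p outside (0,1] at row(s) {rows}")
    zero = df["p"] == 0
    if zero.any():
        logger.warning(
            "%s: %d gene(s) with p=0 clamped to %.1e", path, int(zero.sum()), p_floor
        )
        df.loc[zero, "p"] = p_floor

    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            df[col] = np.nan
    df["chrom"] = df["chrom"].map(_norm_chrom)
    df["start"] = pd.to_numeric(df["start"], errors="coerce")
    df["end"] = pd.to_numeric(df["end"], errors="coerce")

    n_dup = int(df["gene"].duplicated().sum())
    if n_dup:
        logger.warning("%s: %d duplicate gene row(s), keeping smallest p", path, n_dup)
        df = df.sort_values("p", kind="stable").drop_duplicates("gene", keep="first")
    return df.set_index("gene")[["chrom", "start", "end", "p"]].sort_index()


def read_bed_coordinates(path: str | Path, uppercase: bool = True) -> pd.DataFrame:
    """Read gene coordinates from BED (0-based half-open → 1-based inclusive)."""
    bed = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene"], dtype={"chrom": str, "gene": str},
    )
    bed["chrom"] = bed["chrom"].map(_norm_chrom)
    bed["gene"] = bed["gene"].str.strip()
    if uppercase:
        bed["gene"] = bed["gene"].str.upper()
    bed["start"] = bed["start"].astype(int) + 1
    bed["end"] = bed["end"].astype(int)
    return bed.set_index("gene")[["chrom", "start", "end"]]


def exclude_region(
    table: pd.DataFrame,
    chrom: str = MHC_CHROM,
    lo: int = MHC_LO,
    hi: int = MHC_HI,
) -> pd.DataFrame:
    """Drop genes whose interval overlaps [lo, hi] (closed) on ``chrom``.

    Any overlap removes the gene.  Genes without coordinates cannot be
    region-filtered; they are retained with a logged warning.
    """
    if not lo < hi:
        raise ValueError("require lo < hi")
    chrom = _norm_chrom(chrom)
    missing = table["chrom"].isna() | table["start"].isna() | table["end"].isna()
    if missing.any():
        logger.warning(
            "%d gene(s) lack coordinates and cannot be region-filtered", int(missing.sum())
        )
    overlaps = (
        ~missing
        & (table["chrom"] == chrom)
        & (table["start"] <= hi)
        & (table["end"] >= lo)
    )
    return table.loc[~overlaps]


def significant_genes(table: pd.DataFrame, alpha: float) -> set[str]:
    """Genes with p strictly below ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return set(table.index[table["p"] < alpha])


def write_gene_scores(table: pd.DataFrame, path: str | Path) -> None:
    out = table.reset_index()[["gene", "chrom", "start", "end", "p"]].copy()
    for col in ("start", "end"):
        out[col] = out[col].astype("Int64")
    out.to_csv(path, sep="\t", index=False)
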