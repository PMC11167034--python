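"""Receptor/cell table ingest and chain-level quality control.

Chains are carried as a tidy :class:`pandas.DataFrame` with the canonical
columns ``cell_id, contig_id, locus, v_call, j_call, c_call, cdr3_nt,
cdr3_aa, umis, reads, high_confidence, full_length, productive, sequence``;
``read_contigs`` maps both supported dialects onto these names.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TCR_LOCI = ("TRA", "TRB", "TRG", "TRD")
BCR_LOCI = ("IGH", "IGK", "IGL")
ALPHA_LIKE = {"TRA", "TRG"}
BETA_LIKE = {"TRB", "TRD"}

CANONICAL_COLUMNS = [
    "cell_id", "contig_id", "locus", "v_call", "j_call", "c_call",
    "cdr3_nt", "cdr3_aa", "umis", "reads", "high_confidence", "full_length",
    "productive", "sequence",
]

_TENX_MAP = {
    "barcode": "cell_id",
    "contig_id": "contig_id",
    "chain": "locus",
    "v_gene": "v_call",
    "j_gene": "j_call",
    "c_gene": "c_call",
    "cdr3_nt": "cdr3_nt",
    "cdr3": "cdr3_aa",
    "umis": "umis",
    "reads": "reads",
    "high_confidence": "high_confidence",
    "full_length": "full_length",
    "productive": "productive",
}
_TENX_REQUIRED = ("barcode", "chain", "v_gene", "j_gene", "cdr3", "cdr3_nt", "umis")

_AIRR_MAP = {
    "cell_id": "cell_id",
    "sequence_id": "contig_id",
    "locus": "locus",
    "v_call": "v_call",
    "j_call": "j_call",
    "c_call": "c_call",
    "junction": "cdr3_nt",
    "junction_aa": "cdr3_aa",
    "duplicate_count": "umis",
    "consensus_count": "reads",
    "productive": "productive",
    "sequence": "sequence",
}
_AIRR_REQUIRED = ("cell_id", "locus", "v_call", "j_call", "junction", "junction_aa",
                  "duplicate_count")


class FormatError(ValueError):
    """Raised when an input table is missing a required column."""


def _as_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    true_tokens = {"true", "t", "1", "yes"}
    return series.astype(str).str.strip().str.lower().isin(true_tokens)


def read_contigs(path, dialect: str = "tenx_csv") -> pd.DataFrame:
    """Read a contig table (``tenx_csv`` or ``airr_tsv``) into canonical form.

    Unknown columns are ignored; a missing required column raises
    :class:`FormatError` naming it.
    """
    if dialect == "tenx_csv":
        df = pd.read_csv(path)
        required, mapping = _TENX_REQUIRED, _TENX_MAP
    elif dialect == "airr_tsv":
        df = pd.read_csv(path, sep="\t")
        required, mapping = _AIRR_REQUIRED, _AIRR_MAP
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{dialect} contig table is missing required column {col!r}")
    out = pd.DataFrame()
    for src, dst in mapping.items():
        if src in df.columns:
            out[dst] = df[src]
    for col in CANONICAL_COLUMNS:
        if col not in out.columns:
            if col in ("high_confidence", "full_length", "productive"):
                out[col] = True
            elif col in ("umis", "reads"):
                out[col] = 0
            else:
                out[col] = ""
    for col in ("high_confidence", "full_length", "productive"):
        out[col] = _as_bool(out[col])
    out["umis"] = out["umis"].astype(int)
    out["reads"] = out["reads"].fillna(0).astype(int)
    out["sequence"] = out["sequence"].fillna("")
    return out[CANONICAL_COLUMNS]


def read_cells(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ("cell_id", "sample_id", "donor_id", "tissue", "lineage", "subset")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"cell table is missing required column {col!r}")
    if "doublet_flag" in df.columns:
        df["doublet_flag"] = _as_bool(df["doublet_flag"])
    return df


def filter_tcr_chains(chains: pd.DataFrame) -> pd.DataFrame:
    """Retain at most the 2 highest-UMI TCR chains per cell.

    Ties break by reads, then contig id, so output is deterministic.  A cell
    whose retained chains cover only one locus class (alpha-like TRA/TRG vs
    beta-like TRB/TRD) loses all its TCR information.  Non-TCR rows pass
    through untouched.
    """
    is_tcr = chains["locus"].isin(TCR_LOCI)
    tcr = chains[is_tcr].copy()
    other = chains[~is_tcr]
    if tcr.empty:
        return chains.copy()
    tcr = tcr.sort_values(
        ["cell_id", "umis", "reads", "contig_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    tcr = tcr.groupby("cell_id", sort=False).head(2)
    classes = tcr["locus"].map(lambda l: "a" if l in ALPHA_LIKE else "b")
    n_classes = classes.groupby(tcr["cell_id"]).transform("nunique")
    kept = tcr[n_classes == 2]
    removed_cells = tcr.loc[n_classes < 2, "cell_id"].nunique()
    if removed_cells:
        log.info("filter_tcr_chains: removed all TCR info for %d single-class cells",
                 removed_cells)
    return pd.concat([other, kept]).sort_index()


def filter_bcr_chains(
    chains: pd.DataFrame,
    min_cdr3_aa: int = 5,
    min_cdr3_nt: int = 15,
) -> pd.DataFrame:
    """Apply BCR chain QC, then drop all BCR for over-chained cells.

    Chain-level: high-confidence, full-length, CDR3 >= ``min_cdr3_aa``
    residues and >= ``min_cdr3_nt`` nt.  Cell-level: more than two surviving
    heavy chains, or more than two surviving light chains (IGK+IGL), voids
    the cell's BCR entirely.  Non-BCR rows pass through untouched.
    """
    is_bcr = chains["locus"].isin(BCR_LOCI)
    bcr = chains[is_bcr].copy()
    other = chains[~is_bcr]
    if bcr.empty:
        return chains.copy()
    ok = (
        bcr["high_confidence"]
        & bcr["full_length"]
        & (bcr["cdr3_aa"].astype(str).str.len() >= min_cdr3_aa)
        & (bcr["cdr3_nt"].astype(str).str.len() >= min_cdr3_nt)
    )
    bcr = bcr[ok]
    n_heavy = bcr["locus"].eq("IGH").groupby(bcr["cell_id"]).transform("sum")
    n_light = bcr["locus"].isin(("IGK", "IGL")).groupby(bcr["cell_id"]).transform("sum")
    bad = (n_heavy > 2) | (n_light > 2)
    if bad.any():
        log.info("filter_bcr_chains: removed all BCR info for %d over-chained cells",
                 bcr.loc[bad, "cell_id"].nunique())
    bcr = bcr[~bad]
    return pd.concat([other, bcr]).sort_index()


def flag_cross_lineage_doublets(
    cells: pd.DataFrame, chains: pd.DataFrame
) -> pd.DataFrame:
    """Set ``doublet_flag`` where a cell retains >=1 TCR and >=1 BCR chain.

    Also refreshes ``has_tcr``/``has_bcr`` from the retained chains.  Flagged
    cells are excluded from repertoire statistics downstream.
    """
    tcr_cells = set(chains.loc[chains["locus"].isin(TCR_LOCI), "cell_id"])
    bcr_cells = set(chains.loc[chains["locus"].isin(BCR_LOCI), "cell_id"])
    out = cells.copy()
    out["has_tcr"] = out["cell_id"].isin(tcr_cells)
    out["has_bcr"] = out["cell_id"].isin(bcr_cells)
    cross = out["has_tcr"] & out["has_bcr"]
    if "doublet_flag" in out.columns:
        out["doublet_flag"] = out["doublet_flag"].fillna(False).astype(bool) | cross
    else:
        out["doublet_flag"] = cross
    return out


def apply_cell_qc(
    cells: pd.DataFrame,
    min_reads: int = 1000,
    min_genes: int = 500,
    max_mito: float = 0.20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop cells failing any QC threshold; also return per-sample removals.

    Keeps cells with at least ``min_reads`` mapped reads, strictly more than
    ``min_genes`` genes, and strictly less than ``max_mito`` mitochondrial
    fraction.
    """
    keep = (
        (cells["n_reads"] >= min_reads)
        & (cells["n_genes"] > min_genes)
        & (cells["pct_mito"] < max_mito)
    )
    removed = cells[~keep]
    removal_log = (
        removed.groupby("sample_id").size().rename("n_removed").reset_index()
        if len(removed)
        else pd.DataFrame(columns=["sample_id", "n_removed"])
    )
    for _, row in removal_log.iterrows():
        log.info("apply_cell_qc: removed %d cells from %s", row["n_removed"], row["sample_id"])
    return cells[keep].copy(), removal_log


def receptor_recovery(cells: pd.DataFrame, chains: pd.DataFrame) -> pd.Series:
    """Per-sample fraction of cells with any retained receptor chain."""
    with_receptor = cells["cell_id"].isin(chains["cell_id"])
    return with_receptor.groupby(cells["sample_id"]).mean()
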