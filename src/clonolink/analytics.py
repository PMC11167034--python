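"""Clonal expansion, overlap, trafficking and abundance statistics."""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
POSITIVE_AA = ("R", "K")
NEGATIVE_AA = ("D", "E")


def morisita_horn(counts_a, counts_b) -> float | None:
    """Morisita-Horn overlap of two clone count vectors, in [0, 1].

    ``counts_a``/``counts_b`` map clone id -> nonnegative cell count.  An
    empty side is undefined and returns ``None`` rather than 0.
    """
    a = {k: v for k, v in dict(counts_a).items() if v > 0}
    b = {k: v for k, v in dict(counts_b).items() if v > 0}
    if not a or not b:
        return None
    na = sum(a.values())
    nb = sum(b.values())
    cross = sum(a[k] * b[k] for k in a.keys() & b.keys())
    da = sum(v * v for v in a.values()) / (na * na)
    db = sum(v * v for v in b.values()) / (nb * nb)
    return 2.0 * cross / ((da + db) * na * nb)


def overlap_matrix(
    clones, cells: pd.DataFrame, stratum: str | None = None
) -> pd.DataFrame:
    """Pairwise Morisita-Horn overlap between subsets, optionally per tissue.

    Per-subset count vectors are cells per clone (not clone-collapsed).
    Subsets with no clones get missing rows/columns (NaN).
    """
    sub = cells
    if stratum is not None:
        sub = cells[cells["tissue"] == stratum]
    clone_of = clones.clone_of()
    sub = sub[sub["cell_id"].isin(clone_of.index)]
    vectors = {
        subset: Counter(clone_of.loc[grp["cell_id"]])
        for subset, grp in sub.groupby("subset", sort=True)
    }
    subsets = sorted(set(sub["subset"]))
    mat = pd.DataFrame(np.nan, index=subsets, columns=subsets)
    for i, si in enumerate(subsets):
        for sj in subsets[i:]:
            val = morisita_horn(vectors.get(si, {}), vectors.get(sj, {}))
            if val is not None:
                mat.loc[si, sj] = mat.loc[sj, si] = val
    return mat


def expansion_fraction(
    cells: pd.DataFrame,
    clones,
    subset: str,
    tissue: str | None = None,
    min_size: int = 2,
) -> dict:
    """Per-donor fraction of a subset's receptor-bearing cells in clones >= min_size.

    Returns {'per_donor': Series, 'mean': float, 'min': float, 'max': float};
    donors with no assessable cells are excluded from the summary.
    """
    clone_of = clones.clone_of()
    sizes = clones.sizes
    sub = cells[cells["subset"] == subset]
    if tissue is not None:
        sub = sub[sub["tissue"] == tissue]
    sub = sub[sub["cell_id"].isin(clone_of.index)]
    if sub.empty:
        return {"per_donor": pd.Series(dtype=float), "mean": np.nan,
                "min": np.nan, "max": np.nan}
    expanded = clone_of.loc[sub["cell_id"]].map(sizes).ge(min_size).to_numpy()
    per_donor = pd.Series(expanded, index=sub["donor_id"].to_numpy()).groupby(level=0).mean()
    return {"per_donor": per_donor, "mean": float(per_donor.mean()),
            "min": float(per_donor.min()), "max": float(per_donor.max())}


def top_clone_composition(
    clones, cells: pd.DataFrame, n: int = 50, stratum: str = "SYN"
) -> pd.DataFrame:
    """Subset breakdown of the ``n`` largest clones within one tissue.

    Sizes are counted within the stratum (ties broken by clone id); the
    ``shared_other_tissue`` flag marks clones whose id also appears in the
    donor's other tissue.
    """
    clone_of = clones.clone_of()
    merged = cells[cells["cell_id"].isin(clone_of.index)].copy()
    merged["clone_id"] = clone_of.loc[merged["cell_id"]].to_numpy()
    in_stratum = merged[merged["tissue"] == stratum]
    other = merged[merged["tissue"] != stratum]
    other_clones = set(other["clone_id"])
    sizes = in_stratum.groupby("clone_id").size().rename("size")
    top = sizes.sort_values(ascending=False, kind="mergesort")
    top = top.iloc[: min(n, len(top))]
    # stable rank: size desc then clone_id asc
    top = top.reset_index().sort_values(["size", "clone_id"],
                                        ascending=[False, True], kind="mergesort")
    comp = (
        in_stratum[in_stratum["clone_id"].isin(top["clone_id"])]
        .groupby(["clone_id", "subset"]).size().unstack(fill_value=0)
    )
    out = top.set_index("clone_id").join(comp)
    out["shared_other_tissue"] = out.index.isin(other_clones)
    return out.reset_index()


def trafficking_summary(clones, cells: pd.DataFrame) -> pd.DataFrame:
    """Clones present in both tissues of a donor, with per-tissue composition.

    One row per (clone, tissue): clone_id, donor_id, tissue, size plus one
    count column per subset.
    """
    clone_of = clones.clone_of()
    merged = cells[cells["cell_id"].isin(clone_of.index)].copy()
    merged["clone_id"] = clone_of.loc[merged["cell_id"]].to_numpy()
    n_tissues = merged.groupby("clone_id")["tissue"].nunique()
    shared = set(n_tissues[n_tissues == 2].index)
    if not shared:
        return pd.DataFrame(columns=["clone_id", "donor_id", "tissue", "size"])
    sub = merged[merged["clone_id"].isin(shared)]
    comp = (
        sub.groupby(["clone_id", "donor_id", "tissue", "subset"])
        .size().unstack(fill_value=0)
    )
    comp["size"] = comp.sum(axis=1)
    cols = ["size"] + [c for c in comp.columns if c != "size"]
    return comp[cols].reset_index()


def cdr3_properties(chains: pd.DataFrame) -> pd.DataFrame:
    """Per-chain CDR3 amino-acid length and net charge ((#R+#K) - (#D+#E)).

    Empty CDR3s raise; chains containing non-standard residues get NaN
    charge with a warning.
    """
    rows = []
    for _, row in chains.iterrows():
        aa = str(row["cdr3_aa"])
        if not aa:
            raise ValueError(f"empty CDR3 for cell {row['cell_id']}")
        charge: float | None
        if set(aa) - STANDARD_AA:
            warnings.warn(
                f"non-standard residue in CDR3 {aa!r}; excluded from charge",
                stacklevel=2,
            )
            charge = np.nan
        else:
            charge = sum(aa.count(r) for r in POSITIVE_AA) - sum(
                aa.count(r) for r in NEGATIVE_AA
            )
        rows.append({"cell_id": row["cell_id"], "locus": row["locus"],
                     "cdr3_length": len(aa), "cdr3_charge": charge})
    return pd.DataFrame(rows)


@dataclass
class AbundanceResult:
    subset: str
    fractions: pd.DataFrame  # index donor, columns SYN / PBL
    mean_difference: float
    statistic: float
    p_value: float
    method: str = "paired-t"


def subset_fractions(cells: pd.DataFrame, subset: str, lineage: str | None = None
                     ) -> pd.DataFrame:
    """Per donor x tissue fraction of lineage cells belonging to ``subset``."""
    pool = cells
    if lineage is None:
        lineage = pool.loc[pool["subset"] == subset, "lineage"].iloc[0]
    pool = pool[pool["lineage"] == lineage]
    frac = (
        pool.assign(hit=pool["subset"] == subset)
        .groupby(["donor_id", "tissue"])["hit"].mean().unstack()
    )
    return frac


def paired_abundance_test(
    cells: pd.DataFrame, subset: str, lineage: str | None = None,
    method: str = "paired-t",
) -> AbundanceResult:
    """Two-sided paired test of a subset's per-donor SYN vs PBL fractions.

    ``method`` is 'paired-t' (default, matching the published panels) or
    'wilcoxon' (signed-rank).  Fewer than 2 complete donor pairs gives a
    missing p value.
    """
    frac = subset_fractions(cells, subset, lineage)
    for t in ("SYN", "PBL"):
        if t not in frac.columns:
            frac[t] = np.nan
    paired = frac.dropna(subset=["SYN", "PBL"])
    diff = paired["SYN"] - paired["PBL"]
    if len(paired) < 2:
        return AbundanceResult(subset, frac, float(diff.mean()) if len(diff) else np.nan,
                               np.nan, np.nan, method)
    if method == "paired-t":
        res = stats.ttest_rel(paired["SYN"], paired["PBL"])
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(stat) and np.allclose(diff, 0):
            stat, p = 0.0, 1.0  # identical fractions: no evidence of difference
    elif method == "wilcoxon":
        if np.allclose(diff, 0):
            stat, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(paired["SYN"], paired["PBL"])
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return AbundanceResult(subset, frac, float(diff.mean()), stat, p, method)


def holm_correction(p_values: pd.Series) -> pd.Series:
    """Holm step-down adjustment, preserving the input index."""
    from statsmodels.stats.multitest import multipletests

    mask = p_values.notna()
    adj = pd.Series(np.nan, index=p_values.index)
    if mask.any():
        adj.loc[mask] = multipletests(p_values[mask], method="holm")[1]
    return adj
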