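"""Control-binned gene-module scoring and expanded-vs-unexpanded comparisons."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT-style gene-set file: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def module_score(
    expr: pd.DataFrame,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Expression-binned control-subtracted module score per cell.

    ``expr`` is a log-normalized cells x genes frame.  Genes are ranked by
    mean expression over all cells and cut into ``n_bins`` equal-frequency
    bins; each signature gene contributes ``n_ctrl`` control genes drawn
    from its bin (without replacement when the bin is large enough).  The
    score is mean(signature genes) minus mean(all control draws).
    Deterministic given ``seed``.
    """
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    present = [g for g in gene_set if g in expr.columns]
    missing = sorted(set(gene_set) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} signature genes absent from matrix, dropped: "
                      f"{missing[:5]}...", stacklevel=2)
    if not present:
        raise ValueError("no signature genes present in the matrix")
    rng = np.random.default_rng(seed)
    means = expr.mean(axis=0)
    ranks = means.rank(method="first")
    bins = pd.qcut(ranks, q=min(n_bins, len(ranks)), labels=False, duplicates="drop")
    sig_set = set(present)
    # control candidates exclude signature genes: with a small gene universe a
    # bin can be dominated by the signature itself, cancelling the very signal
    # being scored
    bin_members = {
        b: [g for g in means.index[bins == b] if g not in sig_set]
        for b in np.unique(bins)
    }
    controls: list[str] = []
    for gene in present:
        pool = bin_members[int(bins[gene])]
        if not pool:
            pool = list(means.index[bins == int(bins[gene])])
        if len(pool) >= n_ctrl:
            draw = rng.choice(pool, size=n_ctrl, replace=False)
        else:
            draw = rng.choice(pool, size=n_ctrl, replace=True)
        controls.extend(draw)
    sig_mean = expr[present].mean(axis=1)
    ctrl_mean = expr[controls].mean(axis=1)
    return (sig_mean - ctrl_mean).rename("module_score")


def log_normalize(counts, gene_names, cell_ids, target_sum: float | None = None
                  ) -> pd.DataFrame:
    """log1p of size-factor-scaled counts; genes x cells sparse in, cells x genes out."""
    dense = np.asarray(counts.todense()).T.astype(float)  # cells x genes
    totals = dense.sum(axis=1)
    if target_sum is None:
        target_sum = float(np.median(totals[totals > 0]))
    factors = np.where(totals > 0, target_sum / np.maximum(totals, 1), 1.0)
    return pd.DataFrame(np.log1p(dense * factors[:, None]), index=cell_ids,
                        columns=gene_names)


def expanded_vs_unexpanded(
    scores: pd.Series,
    cells: pd.DataFrame,
    clones,
    subset: str,
    tissue: str | None = None,
    min_size: int = 2,
) -> dict:
    """Per-donor paired comparison of module scores by clonal expansion.

    For each donor, the mean score over expanded (clone size >= ``min_size``)
    and unexpanded cells of ``subset``; donors missing either group are
    excluded from the two-sided paired t-test.
    """
    clone_of = clones.clone_of()
    sizes = clones.sizes
    sub = cells[cells["subset"] == subset]
    if tissue is not None:
        sub = sub[sub["tissue"] == tissue]
    sub = sub[sub["cell_id"].isin(clone_of.index) & sub["cell_id"].isin(scores.index)]
    expanded = clone_of.loc[sub["cell_id"]].map(sizes).ge(min_size).to_numpy()
    df = pd.DataFrame({
        "donor_id": sub["donor_id"].to_numpy(),
        "score": scores.loc[sub["cell_id"]].to_numpy(),
        "expanded": expanded,
    })
    per_donor = df.groupby(["donor_id", "expanded"])["score"].mean().unstack()
    for col in (True, False):
        if col not in per_donor.columns:
            per_donor[col] = np.nan
    paired = per_donor.dropna()
    result = {
        "per_donor": per_donor.rename(columns={True: "expanded", False: "unexpanded"}),
        "n_pairs": int(len(paired)),
        "mean_difference": float((paired[True] - paired[False]).mean())
        if len(paired) else np.nan,
        "statistic": np.nan,
        "p_value": np.nan,
    }
    if len(paired) >= 2:
        t = stats.ttest_rel(paired[True], paired[False])
        result["statistic"] = float(t.statistic)
        result["p_value"] = float(t.pvalue)
    return result
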