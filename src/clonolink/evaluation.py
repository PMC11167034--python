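"""Parameter-recovery evaluation on replicate synthetic cohorts.

Runs the actual pipeline stages (contig parsing, chain QC, doublet flagging,
cell QC, clonotyping, isotype classification) on freshly generated
paper-default cohorts and summarizes the cohort-level quantities that the
source study prints, so generator + pipeline can be validated end to end by
parameter recovery.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from . import analytics, clonotyping, ingest, shm
from .config import CohortConfig, paper_default
from .simulate import Cohort, generate_cohort

TARGET_COLUMNS = ["t1", "t2", "t3", "t4", "t5", "t6", "t7", "t8", "t9", "t10"]


def qc_cohort(cohort: Cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ingest a cohort's AIRR table through the full QC path."""
    buf = io.StringIO()
    cohort.airr.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    chains = ingest.read_contigs(buf, "airr_tsv")
    chains = ingest.filter_tcr_chains(chains)
    chains = ingest.filter_bcr_chains(chains)
    cells = ingest.flag_cross_lineage_doublets(cohort.cells, chains)
    cells, _ = ingest.apply_cell_qc(cells)
    chains = chains[chains["cell_id"].isin(cells["cell_id"])]
    return cells, chains


def _naive_fraction(cells: pd.DataFrame, tissue: str, prefix: str,
                    naive_label: str) -> float:
    """Mean over samples of one tissue of naive/(lineage pool) fractions."""
    pool = cells[cells["subset"].str.startswith(prefix)
                 & (cells["tissue"] == tissue)]
    per_sample = (pool["subset"] == naive_label).groupby(pool["sample_id"]).mean()
    return float(per_sample.mean())


def compute_targets(cohort: Cohort) -> dict[str, float]:
    """t1..t10 for one cohort, on the percent scale the study prints."""
    cells, chains = qc_cohort(cohort)
    out: dict[str, float] = {}
    out["t1"] = 100 * _naive_fraction(cells, "PBL", "CD4", "CD4-naive")
    out["t2"] = 100 * _naive_fraction(cells, "SYN", "CD4", "CD4-naive")
    tcr = clonotyping.call_tcr_clones(cells, chains)
    out["t3"] = 100 * analytics.expansion_fraction(
        cells, tcr, "CD4-Tph", tissue="SYN")["mean"]
    out["t4"] = 100 * _naive_fraction(cells, "PBL", "B", "B-naive")
    out["t5"] = 100 * _naive_fraction(cells, "SYN", "B", "B-naive")
    recovery = ingest.receptor_recovery(cells, chains)
    tissue_of = cells.groupby("sample_id")["tissue"].first()
    out["t6"] = 100 * float(recovery[tissue_of == "SYN"].mean())
    out["t7"] = 100 * float(recovery[tissue_of == "PBL"].mean())
    igh = chains[chains["locus"] == "IGH"]
    states = shm.classify_switch(igh).merge(
        cells[["cell_id", "subset"]], on="cell_id")
    states = states[~states["excluded"]]
    for tid, subset in (("t8", "B-memory"), ("t9", "B-ABC"),
                        ("t10", "B-activated")):
        sub = states[states["subset"] == subset]
        out[tid] = 100 * float(sub["switched"].astype(bool).mean())
    return out


def replicate_targets(
    seed: int,
    n_replicates: int = 20,
    config_factory=None,
) -> pd.DataFrame:
    """t1..t10 for ``n_replicates`` cohorts seeded from ``seed``."""
    if config_factory is None:
        def config_factory(s: int) -> CohortConfig:
            return paper_default(seed=s, include_expression=False)
    rows = []
    for i in range(n_replicates):
        cohort = generate_cohort(config_factory(seed + 1000 * i))
        rows.append(compute_targets(cohort))
    return pd.DataFrame(rows, columns=TARGET_COLUMNS)


def summarize_targets(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Mean, SE over replicates and replicate count per target."""
    n = len(per_replicate)
    return pd.DataFrame({
        "value": per_replicate.mean(),
        "se": per_replicate.std(ddof=1) / np.sqrt(n),
        "n": n,
    })
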