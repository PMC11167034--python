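import io

import pandas as pd
import pytest

from clonolink import generate_cohort
from clonolink.config import shared_pool_overlap_config
from clonolink import ingest


@pytest.fixture(scope="session")
def small_cohort():
    """A small paper-style cohort (4 donors, 3 with blood) with all artifacts."""
    return generate_cohort(shared_pool_overlap_config(seed=11))


@pytest.fixture(scope="session")
def ingested(small_cohort):
    """(cells, chains) after full chain + cell QC, as the pipeline produces."""
    buf = io.StringIO()
    small_cohort.airr.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    chains = ingest.read_contigs(buf, "airr_tsv")
    chains = ingest.filter_tcr_chains(chains)
    chains = ingest.filter_bcr_chains(chains)
    cells = ingest.flag_cross_lineage_doublets(small_cohort.cells, chains)
    cells, _ = ingest.apply_cell_qc(cells)
    chains = chains[chains["cell_id"].isin(cells["cell_id"])]
    return cells, chains


def make_chains(rows):
    """Build a canonical chain table from compact dicts (test helper)."""
    defaults = {
        "contig_id": "", "v_call": "V1", "j_call": "J1", "c_call": "",
        "cdr3_nt": "TGTGCAAGC", "cdr3_aa": "CAS", "umis": 1, "reads": 10,
        "high_confidence": True, "full_length": True, "productive": True,
        "sequence": "",
    }
    out = []
    for i, row in enumerate(rows):
        rec = {**defaults, **row}
        if not rec["contig_id"]:
            rec["contig_id"] = f"{rec['cell_id']}_contig_{i + 1}"
        out.append(rec)
    return pd.DataFrame(out, columns=ingest.CANONICAL_COLUMNS)


def make_cells(rows):
    defaults = {
        "sample_id": "D01-SYN", "donor_id": "D01", "tissue": "SYN",
        "lineage": "T", "subset": "CD4-naive", "n_reads": 5000,
        "n_genes": 1500, "pct_mito": 0.05, "doublet_flag": False,
        "has_tcr": False, "has_bcr": False,
    }
    return pd.DataFrame([{**defaults, **row} for row in rows])
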