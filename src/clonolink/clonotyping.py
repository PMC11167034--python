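"""Clone calling for TCR (exact key) and BCR (CDR3 identity clustering)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError
from .ingest import BCR_LOCI, TCR_LOCI

SIZE_BINS = ((1, 1, "singleton"), (2, 5, "small"), (6, 19, "medium"),
             (20, 100, "large"), (101, None, "hyperexpanded"))

SIZE_CATEGORIES = [name for _, _, name in SIZE_BINS]


def size_category(size: int) -> str:
    for lo, hi, name in SIZE_BINS:
        if size >= lo and (hi is None or size <= hi):
            return name
    raise ValueError(f"bad clone size {size}")


@dataclass
class CloneTable:
    """Cell -> clone assignment under a stated definition.

    ``assignments`` has columns ``cell_id, clone_id``; sizes and size
    categories are derived.  Clone ids never span donors (they are prefixed
    with the donor id).
    """

    assignments: pd.DataFrame
    definition: dict = field(default_factory=dict)

    @property
    def sizes(self) -> pd.Series:
        return self.assignments.groupby("clone_id").size().rename("size")

    @property
    def size_categories(self) -> pd.Series:
        return self.sizes.map(size_category).rename("size_category")

    def clone_of(self) -> pd.Series:
        return self.assignments.set_index("cell_id")["clone_id"]

    def to_frame(self) -> pd.DataFrame:
        """Flat per-cell table with clone id, size and size category."""
        df = self.assignments.copy()
        sizes = self.sizes
        df["size"] = df["clone_id"].map(sizes)
        df["size_category"] = df["size"].map(size_category)
        for k, v in self.definition.items():
            df[f"def_{k}"] = str(v)
        return df


def _eligible_cells(cells: pd.DataFrame) -> pd.DataFrame:
    if "doublet_flag" in cells.columns:
        return cells[~cells["doublet_flag"].astype(bool)]
    return cells


def call_tcr_clones(cells: pd.DataFrame, chains: pd.DataFrame) -> CloneTable:
    """Group cells with an identical TCR within each donor into clones.

    The clone key is the sorted tuple of (locus, v_call, j_call, cdr3_nt)
    over the cell's retained TCR chains, so both chains (when present) must
    match exactly.
    """
    eligible = _eligible_cells(cells)
    donor_of = dict(zip(eligible["cell_id"], eligible["donor_id"]))
    tcr = chains[chains["locus"].isin(TCR_LOCI) & chains["cell_id"].isin(donor_of)]
    keys: dict[str, tuple] = {}
    for cell_id, grp in tcr.groupby("cell_id", sort=True):
        keys[cell_id] = tuple(
            sorted(zip(grp["locus"], grp["v_call"], grp["j_call"], grp["cdr3_nt"]))
        )
    clone_ids: dict[tuple, str] = {}
    rows = []
    for cell_id in sorted(keys):
        full_key = (donor_of[cell_id], keys[cell_id])
        if full_key not in clone_ids:
            clone_ids[full_key] = f"{donor_of[cell_id]}:TCR{len(clone_ids):05d}"
        rows.append({"cell_id": cell_id, "clone_id": clone_ids[full_key]})
    assignments = pd.DataFrame(rows, columns=["cell_id", "clone_id"])
    return CloneTable(assignments, {"receptor": "TCR", "threshold": "exact",
                                    "partition": "donor"})


def _best_matches(a: "np.ndarray", b: "np.ndarray") -> int:
    """Maximal match count of the shorter array slid along the longer."""
    if len(a) < len(b):
        a, b = b, a
    best = 0
    for off in range(len(a) - len(b) + 1):
        m = int((a[off : off + len(b)] == b).sum())
        if m > best:
            best = m
    return best


def cdr3_identity(a: str, b: str, denominator: str = "longer") -> float:
    """Ungapped identity at the best offset of the shorter inside the longer.

    ``denominator``: 'longer' (conservative, default) or 'shorter' (the
    greedy-clustering tool's convention).
    """
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    denom = max(len(a), len(b)) if denominator == "longer" else min(len(a), len(b))
    return _best_matches(arr_a, arr_b) / denom


def greedy_cluster(
    sequences: list[str],
    counts: list[int],
    threshold: float,
    denominator: str = "longer",
) -> dict[str, int]:
    """CD-HIT-style greedy centroid clustering of unique sequences.

    Sequences are processed by descending length, then descending count,
    then lexicographically; each joins the first cluster whose founding
    representative is >= ``threshold`` identical, else founds a new cluster.
    Returns sequence -> cluster index.
    """
    order = sorted(
        range(len(sequences)), key=lambda i: (-len(sequences[i]), -counts[i], sequences[i])
    )
    encoded = {s: np.frombuffer(s.encode(), dtype=np.uint8) for s in sequences}
    reps: list[str] = []
    label: dict[str, int] = {}
    for i in order:
        seq = sequences[i]
        arr = encoded[seq]
        for ci, rep in enumerate(reps):
            lo, hi = min(len(seq), len(rep)), max(len(seq), len(rep))
            denom = hi if denominator == "longer" else lo
            if lo / denom < threshold:  # identity can never reach threshold
                continue
            if _best_matches(arr, encoded[rep]) / denom >= threshold:
                label[seq] = ci
                break
        else:
            label[seq] = len(reps)
            reps.append(seq)
    return label


def call_bcr_clones(
    cells: pd.DataFrame,
    chains: pd.DataFrame,
    threshold: float = 0.965,
    denominator: str = "longer",
) -> CloneTable:
    """Cluster B cells into clones by IgH CDR3 nucleotide identity per donor.

    Uses the cell's highest-UMI IGH chain.  ``threshold`` is the minimum
    identity to a cluster representative (the published analysis uses 0.965,
    with 0.80 as the relaxed re-analysis value).
    """
    if not 0 < threshold <= 1:
        raise ConfigurationError(f"threshold {threshold} outside (0, 1]")
    eligible = _eligible_cells(cells)
    donor_of = dict(zip(eligible["cell_id"], eligible["donor_id"]))
    igh = chains[(chains["locus"] == "IGH") & chains["cell_id"].isin(donor_of)]
    igh = igh.sort_values(["cell_id", "umis", "contig_id"],
                          ascending=[True, False, True], kind="mergesort")
    igh = igh.groupby("cell_id", sort=True).head(1)
    rows = []
    for donor, grp in igh.groupby(igh["cell_id"].map(donor_of), sort=True):
        seq_counts = grp["cdr3_nt"].value_counts()
        seqs = list(seq_counts.index)
        label = greedy_cluster(seqs, [int(seq_counts[s]) for s in seqs],
                               threshold, denominator)
        for cell_id, seq in zip(grp["cell_id"], grp["cdr3_nt"]):
            rows.append({"cell_id": cell_id,
                         "clone_id": f"{donor}:BCR{label[seq]:05d}"})
    assignments = pd.DataFrame(rows, columns=["cell_id", "clone_id"])
    return CloneTable(assignments, {"receptor": "BCR", "threshold": threshold,
                                    "partition": "donor",
                                    "denominator": denominator})


def categorize_clone_sizes(table: CloneTable) -> pd.DataFrame:
    """Per-clone size and size-category table ({1},{2-5},{6-19},{20-100},{>100})."""
    df = table.sizes.reset_index()
    df["size_category"] = df["size"].map(size_category)
    return df


def flag_invariant_mait(chains: pd.DataFrame) -> pd.Series:
    """True per cell iff a retained TRA chain uses TRAV1-2 with TRAJ33/20/12."""
    tra = chains[chains["locus"] == "TRA"]
    strip = lambda g: str(g).split("*")[0]
    hit = tra["v_call"].map(strip).eq("TRAV1-2") & tra["j_call"].map(strip).isin(
        ("TRAJ33", "TRAJ20", "TRAJ12")
    )
    flags = hit.groupby(tra["cell_id"]).any()
    all_cells = pd.Index(chains["cell_id"].unique())
    return flags.reindex(all_cells, fill_value=False).rename("is_mait")
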