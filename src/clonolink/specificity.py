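"""HLA-restricted viral-specificity matching for CD8 TCRbeta chains.

Two routes: exact CDR3beta + HLA matching against a reference table, and a
simplified motif-enrichment route (contiguous interior k-mers, one-sided
Fisher enrichment of reference + sample clones over a background repertoire,
retained only with a reference member, a sample member and a donor HLA
match).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

N_TERM_TRIM = 3
C_TERM_TRIM = 2


def _two_field(allele: str) -> str:
    """Truncate an HLA allele to two-field resolution (A*02:01:05 -> A*02:01)."""
    gene, _, rest = allele.partition("*")
    fields = rest.split(":")
    return f"{gene}*{':'.join(fields[:2])}"


def load_hla(hla: pd.DataFrame) -> dict[str, set]:
    """Donor -> set of carried two-field alleles from a long-format table."""
    return {
        donor: {_two_field(a) for a in grp["allele"]}
        for donor, grp in hla.groupby("donor_id")
    }


def exact_match(
    chains: pd.DataFrame,
    reference: pd.DataFrame,
    cells: pd.DataFrame,
    hla: pd.DataFrame,
) -> pd.DataFrame:
    """Exact CDR3beta + HLA matches of TRB chains against the reference.

    A cell matches a reference row iff its TRB CDR3 amino-acid sequence
    equals the row's and the row's MHC allele is carried by the cell's
    donor.  Cells of donors absent from the HLA table are skipped with a
    warning.  A cell matching several rows keeps all matches.
    """
    carried = load_hla(hla)
    donor_of = dict(zip(cells["cell_id"], cells["donor_id"]))
    trb = chains[chains["locus"] == "TRB"]
    by_cdr3: dict[str, list] = {}
    for idx, row in reference.iterrows():
        by_cdr3.setdefault(row["cdr3b_aa"], []).append(
            (row["virus"], row["epitope"], _two_field(row["mhc_allele"]))
        )
    missing_donors = set()
    rows = []
    for _, chain in trb.iterrows():
        cell_id = chain["cell_id"]
        donor = donor_of.get(cell_id)
        if donor not in carried:
            missing_donors.add(donor)
            continue
        for virus, epitope, allele in by_cdr3.get(str(chain["cdr3_aa"]), []):
            if allele in carried[donor]:
                rows.append({"cell_id": cell_id, "donor_id": donor,
                             "cdr3b_aa": chain["cdr3_aa"], "virus": virus,
                             "epitope": epitope, "mhc_allele": allele})
    if missing_donors:
        warnings.warn(f"donors absent from HLA table skipped: {sorted(missing_donors)}",
                      stacklevel=2)
    return pd.DataFrame(rows, columns=["cell_id", "donor_id", "cdr3b_aa", "virus",
                                       "epitope", "mhc_allele"])


def interior_kmers(cdr3_aa: str, k: int) -> list[str]:
    """Contiguous k-mers of the CDR3 interior (trim 3 N-term, 2 C-term residues)."""
    interior = cdr3_aa[N_TERM_TRIM: len(cdr3_aa) - C_TERM_TRIM]
    return [interior[i: i + k] for i in range(len(interior) - k + 1)]


@dataclass
class MotifGroup:
    motif: str
    virus: str
    reference_members: list
    sample_members: list  # clone ids
    background_count: int
    fisher_p: float
    hla_restriction: str | None
    retained: bool
    matched_sample_members: list = field(default_factory=list)


def motif_match(
    sample_clones: pd.DataFrame,
    reference: pd.DataFrame,
    background_cdr3s: list[str],
    hla: pd.DataFrame,
    k: int = 3,
    p_cut: float = 0.01,
) -> tuple[list[MotifGroup], pd.DataFrame]:
    """Motif-level viral matching of sample CD8 clones.

    ``sample_clones`` needs columns ``clone_id, donor_id, cdr3b_aa`` (one row
    per clone).  Per virus, every interior k-mer seen in the foreground
    (reference rows of that virus plus sample clones) is tested one-sided
    (Fisher exact, greater) for enrichment over the background clone set; a
    group is retained iff fisher_p < ``p_cut``, it has at least one
    reference member and one sample member, and at least one sample member's
    donor carries an HLA allele of a reference member.

    Returns the groups plus a per-clone flag table (clone_id, motif_matched).
    """
    if len(background_cdr3s) == 0:
        raise ValueError("background clone set is empty")
    carried = load_hla(hla)
    bg_sets = [set(interior_kmers(s, k)) for s in background_cdr3s]
    n_bg = len(bg_sets)

    groups: list[MotifGroup] = []
    matched_clones: set = set()
    for virus, ref_rows in reference.groupby("virus", sort=True):
        ref_motifs: dict[str, list] = {}
        for idx, row in ref_rows.iterrows():
            for m in set(interior_kmers(str(row["cdr3b_aa"]), k)):
                ref_motifs.setdefault(m, []).append(idx)
        sample_motifs: dict[str, list] = {}
        for _, row in sample_clones.iterrows():
            for m in set(interior_kmers(str(row["cdr3b_aa"]), k)):
                sample_motifs.setdefault(m, []).append(row["clone_id"])
        donors_of_clone = dict(zip(sample_clones["clone_id"], sample_clones["donor_id"]))
        n_fg = len(ref_rows) + len(sample_clones)
        for motif in sorted(set(ref_motifs) | set(sample_motifs)):
            ref_members = ref_motifs.get(motif, [])
            samp_members = sample_motifs.get(motif, [])
            a = len(ref_members) + len(samp_members)
            b = sum(motif in s for s in bg_sets)
            _, p = stats.fisher_exact([[a, n_fg - a], [b, n_bg - b]],
                                      alternative="greater")
            hla_hits = []
            ref_alleles = {_two_field(ref_rows.at[i, "mhc_allele"]) for i in ref_members}
            for cid in samp_members:
                donor = donors_of_clone.get(cid)
                if donor in carried and carried[donor] & ref_alleles:
                    hla_hits.append(cid)
            retained = (
                p < p_cut
                and len(ref_members) >= 1
                and len(samp_members) >= 1
                and len(hla_hits) >= 1
            )
            if retained:
                matched_clones.update(hla_hits)
            groups.append(MotifGroup(
                motif=motif, virus=virus,
                reference_members=list(ref_members),
                sample_members=list(samp_members),
                background_count=int(b), fisher_p=float(p),
                hla_restriction=sorted(ref_alleles)[0] if ref_alleles else None,
                retained=retained, matched_sample_members=hla_hits,
            ))
    flags = pd.DataFrame({
        "clone_id": sample_clones["clone_id"],
        "motif_matched": sample_clones["clone_id"].isin(matched_clones),
    })
    return groups, flags


def compare_matching_phenotypes(
    match_flags: pd.Series,
    cells: pd.DataFrame,
    clones,
) -> dict:
    """Subset and clone-size comparisons of matching vs non-matching cells.

    ``match_flags`` is indexed by cell_id.  Per tissue: a subset x matching
    contingency table with a chi-square test; plus side-by-side clone-size
    category distributions.  Strata without both groups are omitted.
    """
    from .clonotyping import size_category

    flagged = cells[cells["cell_id"].isin(match_flags.index)].copy()
    flagged["matched"] = match_flags.loc[flagged["cell_id"]].to_numpy()
    out: dict = {"by_tissue": {}}
    for tissue, grp in flagged.groupby("tissue", sort=True):
        if grp["matched"].nunique() < 2:
            continue
        table = pd.crosstab(grp["subset"], grp["matched"])
        usable = table.loc[table.sum(axis=1) > 0]
        chi2, p, dof, _ = stats.chi2_contingency(usable)
        out["by_tissue"][tissue] = {
            "contingency": table, "chi2": float(chi2), "p_value": float(p), "dof": int(dof),
        }
    clone_of = clones.clone_of()
    sizes = clones.sizes
    with_clone = flagged[flagged["cell_id"].isin(clone_of.index)].copy()
    if len(with_clone):
        cat = clone_of.loc[with_clone["cell_id"]].map(sizes).map(size_category)
        out["clone_size_categories"] = pd.crosstab(cat.to_numpy(),
                                                   with_clone["matched"].to_numpy())
    return out
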