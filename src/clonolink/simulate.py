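"""Synthetic paired-cohort generator with ground truth.

Generates cell metadata, 10x-style contig and AIRR rearrangement tables, a
count matrix, a germline reference, donor HLA assignments and a viral TCR
reference table, all from one seeded :class:`~clonolink.config.CohortConfig`.
Every stochastic choice flows from the config seed, so a fixed seed yields
bit-identical outputs.

Generative model, in order:

1. cells are partitioned into samples (SYN for all donors, PBL for the first
   ``n_blood_donors``), with per-cell subsets drawn from the per-tissue
   composition map;
2. receptor recovery is sampled per cell at the tissue's recovery
   probability; clone membership is then sampled among *recovered* cells so
   expansion fractions are defined on the receptor-bearing population, which
   is the population on which they are ever measured;
3. expanded clones are sized by a truncated geometric distribution on
   sizes >= 2; a configured fraction of expanded clones is re-emitted in the
   donor's other tissue (trafficking);
4. a subset of CD8 clones receives CDR3beta sequences copied verbatim from
   the viral reference, restricted to an HLA allele its donor carries;
5. TCR clone members share nucleotide-identical chains; BCR clone members
   share germline V/J and CDR3 but draw independent per-site substitutions
   outside the CDR3 at the subset's SHM rate; isotypes are drawn from the
   subset switch probability with a donor-level logit offset;
6. counts are overdispersed (lognormal-Poisson); signature genes gain a
   configured log-scale effect in expanded cells of the designated subset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import germline
from ._util import derive_rng, random_cdr3_nt, translate_nt
from .config import B_SUBSETS, CohortConfig, T_SUBSETS

HLA_POOL = (
    "A*01:01", "A*02:01", "A*03:01",
    "B*07:02", "B*08:01", "B*27:05",
    "C*04:01", "C*07:01", "C*07:02",
)

_AA_TO_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "AGC", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

_CDR3_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _backtranslate(aa: str) -> str:
    return "".join(_AA_TO_CODON[c] for c in aa)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass
class _Clone:
    clone_id: str
    donor: str
    lineage: str
    subset: str
    members: dict = field(default_factory=dict)  # tissue -> [cell_id]
    receptor: dict = field(default_factory=dict)  # locus -> (v, j, cdr3_nt)

    @property
    def size(self) -> int:
        return sum(len(v) for v in self.members.values())

    @property
    def tissues(self) -> set:
        return {t for t, v in self.members.items() if v}


@dataclass
class GroundTruth:
    """Generator-side truth for every emitted receptor-bearing cell."""

    clone_of: dict  # cell_id -> clone_id
    clone_tissues: dict  # clone_id -> frozenset of tissues
    germline_of: dict  # cell_id -> (v_call, j_call, v_mut_positions, j_mut_positions)
    isotype_of: dict  # B cell_id -> isotype label
    expanded: dict  # cell_id -> bool (clone size >= 2)
    viral_cells: list  # cell ids in planted viral-match clones
    viral_clones: list  # planted clone ids
    donor_switch_offsets: dict  # donor -> logit offset
    params: dict  # realized per-subset parameters


@dataclass
class Cohort:
    cells: pd.DataFrame
    contigs: pd.DataFrame  # 10x filtered-contig dialect
    airr: pd.DataFrame  # AIRR rearrangement dialect
    counts: sparse.csr_matrix | None  # genes x cells
    gene_names: list
    germline_fasta: str
    hla: pd.DataFrame
    viral_reference: pd.DataFrame
    truth: GroundTruth
    config: CohortConfig


def _partition_clones(cell_ids, frac, cont, rng):
    """Split cells into clone member groups; expanded clones sized 2+Geom."""
    ids = list(cell_ids)
    n = len(ids)
    if n == 0:
        return []
    expanded_mask = rng.random(n) < frac
    exp_ids = [c for c, m in zip(ids, expanded_mask) if m]
    single = [c for c, m in zip(ids, expanded_mask) if not m]
    if len(exp_ids) == 1:  # a lone "expanded" cell cannot form a clone
        single.append(exp_ids.pop())
    rng.shuffle(exp_ids)
    groups = []
    i = 0
    while i < len(exp_ids):
        size = 2 + int(rng.geometric(1.0 - cont)) - 1 if cont > 0 else 2
        if len(exp_ids) - i - size == 1:  # avoid stranding a single cell
            size += 1
        size = min(size, len(exp_ids) - i)
        groups.append(exp_ids[i : i + size])
        i += size
    groups.extend([[c] for c in single])
    return groups


def _make_viral_reference(n_rows, rng, family_size: int = 4) -> pd.DataFrame:
    """Reference TCRs in epitope families sharing an interior 5-mer motif.

    Epitope-specific TCRs recur around shared CDR3 motifs; grouping rows this
    way gives motif-level matching a realistic recurrence structure (a single
    unique CDR3 per epitope would make every motif a singleton).
    """
    viruses = ("CMV", "EBV", "FLU")
    seen = set()
    rows = []
    fam = -1
    while len(rows) < n_rows:
        fam += 1
        motif = "".join(rng.choice(_CDR3_AA, size=5))
        virus = viruses[int(rng.integers(3))]
        allele = HLA_POOL[int(rng.integers(len(HLA_POOL)))]
        for _ in range(min(family_size, n_rows - len(rows))):
            while True:
                left = "".join(rng.choice(_CDR3_AA, size=3))
                right = "".join(rng.choice(_CDR3_AA, size=int(rng.integers(3, 6))))
                aa = "C" + left + motif + right + "F"
                if aa not in seen:
                    seen.add(aa)
                    break
            rows.append(
                {
                    "cdr3b_aa": aa,
                    "virus": virus,
                    "epitope": f"EPI{fam:03d}",
                    "mhc_allele": allele,
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate one synthetic cohort; see the module docstring for the model."""
    config.validate()
    seed = config.seed
    rng_cells = derive_rng(seed, "cells")
    rng_clones = derive_rng(seed, "clones")
    rng_chains = derive_rng(seed, "chains")
    rng_traffic = derive_rng(seed, "trafficking")
    rng_viral = derive_rng(seed, "viral")
    rng_expr = derive_rng(seed, "expression")
    rng_donor = derive_rng(seed, "donor-effects")

    donors = [f"D{i + 1:02d}" for i in range(config.n_donors)]
    blood_donors = set(donors[: config.n_blood_donors])
    donor_hla = {
        d: sorted(
            list(rng_donor.choice(HLA_POOL[0:3], size=2, replace=False))
            + list(rng_donor.choice(HLA_POOL[3:6], size=2, replace=False))
            + list(rng_donor.choice(HLA_POOL[6:9], size=2, replace=False))
        )
        for d in donors
    }
    switch_offsets = {d: float(rng_donor.normal(0.0, config.donor_sd_switch)) for d in donors}
    shm_offsets = {d: float(rng_donor.normal(0.0, config.donor_sd_shm)) for d in donors}

    # ---- cells ---------------------------------------------------------
    cell_rows = []
    for donor in donors:
        tissues = ["SYN"] + (["PBL"] if donor in blood_donors else [])
        for tissue in tissues:
            sample_id = f"{donor}-{tissue}"
            comp = config.composition[tissue]
            for lineage, subsets, n_cells in (
                ("T", T_SUBSETS, config.cells_per_sample_T),
                ("B", B_SUBSETS, config.cells_per_sample_B),
            ):
                probs = np.array([comp.get(s, 0.0) for s in subsets])
                probs = probs / probs.sum()
                drawn = rng_cells.choice(len(subsets), size=n_cells, p=probs)
                recovered = rng_cells.random(n_cells) < config.recovery_prob[tissue]
                n_reads = rng_cells.integers(1500, 30000, size=n_cells)
                n_genes = rng_cells.integers(600, 3000, size=n_cells)
                pct_mito = rng_cells.uniform(0.0, 0.15, size=n_cells)
                for i in range(n_cells):
                    cell_rows.append(
                        {
                            "cell_id": f"{sample_id}-{lineage}{i:05d}",
                            "sample_id": sample_id,
                            "donor_id": donor,
                            "tissue": tissue,
                            "lineage": lineage,
                            "subset": subsets[drawn[i]],
                            "n_reads": int(n_reads[i]),
                            "n_genes": int(n_genes[i]),
                            "pct_mito": float(pct_mito[i]),
                            "doublet_flag": False,
                            "_recovered": bool(recovered[i]),
                        }
                    )
    cells = pd.DataFrame(cell_rows)

    counts = None
    gene_names: list = []
    contigs = pd.DataFrame()
    airr = pd.DataFrame()
    truth = GroundTruth({}, {}, {}, {}, {}, [], [], switch_offsets, {})
    viral_reference = pd.DataFrame(
        columns=["cdr3b_aa", "virus", "epitope", "mhc_allele"]
    )

    clones: dict[str, _Clone] = {}
    if config.include_receptors:
        clones = _build_clones(config, cells, rng_clones)
        _apply_trafficking(config, cells, clones, rng_traffic)
        if config.viral_plant[0] > 0:
            viral_reference = _make_viral_reference(config.viral_plant[0], rng_viral)
            _plant_viral_matches(config, clones, viral_reference, donor_hla, truth, rng_viral)
        contigs, airr = _emit_chains(
            config, cells, clones, switch_offsets, shm_offsets, truth, rng_chains
        )
        for clone in clones.values():
            truth.clone_tissues[clone.clone_id] = frozenset(clone.tissues)
            expanded = clone.size >= 2
            for members in clone.members.values():
                for cid in members:
                    truth.clone_of[cid] = clone.clone_id
                    truth.expanded[cid] = expanded
        has_rec = cells["cell_id"].isin(truth.clone_of.keys())
        cells["has_tcr"] = has_rec & (cells["lineage"] == "T")
        cells["has_bcr"] = has_rec & (cells["lineage"] == "B")
    else:
        cells["has_tcr"] = False
        cells["has_bcr"] = False

    if config.include_expression and config.expression is not None:
        counts, gene_names = _make_expression(config, cells, truth, rng_expr)

    cells = cells.drop(columns=["_recovered"])
    truth.params = _realized_params(config, cells, truth)

    hla = pd.DataFrame(
        [{"donor_id": d, "allele": a} for d in donors for a in donor_hla[d]]
    )
    return Cohort(
        cells=cells,
        contigs=contigs,
        airr=airr,
        counts=counts,
        gene_names=gene_names,
        germline_fasta=germline.reference_fasta(),
        hla=hla,
        viral_reference=viral_reference,
        truth=truth,
        config=config,
    )


def _build_clones(config, cells, rng) -> dict[str, _Clone]:
    """Partition recovered cells into clones and assign clone receptors."""
    ref_v = {loc: germline.reference_segments(loc, "V") for loc in germline.LOCI}
    ref_j = {loc: germline.reference_segments(loc, "J") for loc in germline.LOCI}
    tra_v_pool = [f"TRAV{i}" for i in range(2, 13)]
    tra_j_pool = [f"TRAJ{i}" for i in range(1, 31) if i not in (12, 20)]
    trb_v_pool = [f"TRBV{i}" for i in range(2, 13)]
    trb_j_pool = [f"TRBJ1-{i}" for i in range(1, 7)]
    mait_j = ("TRAJ33", "TRAJ20", "TRAJ12")

    clones: dict[str, _Clone] = {}
    counter: dict[str, int] = {}
    recovered = cells[cells["_recovered"]]
    for (donor, tissue, lineage, subset), grp in recovered.groupby(
        ["donor_id", "tissue", "lineage", "subset"], sort=True
    ):
        frac, cont = config.expansion.get(subset, (0.0, 0.5))
        groups = _partition_clones(grp["cell_id"].tolist(), frac, cont, rng)
        for members in groups:
            counter.setdefault(donor, 0)
            counter[donor] += 1
            cid = f"{donor}:{lineage}{counter[donor]:05d}"
            clone = _Clone(cid, donor, lineage, subset)
            clone.members[tissue] = list(members)
            if lineage == "T":
                if subset == "MAIT":
                    va = "TRAV1-2"
                    ja = mait_j[int(rng.integers(3))]
                else:
                    va = tra_v_pool[int(rng.integers(len(tra_v_pool)))]
                    ja = tra_j_pool[int(rng.integers(len(tra_j_pool)))]
                clone.receptor = {
                    "TRA": (va, ja, random_cdr3_nt(rng, int(rng.integers(10, 21)))),
                    "TRB": (
                        trb_v_pool[int(rng.integers(len(trb_v_pool)))],
                        trb_j_pool[int(rng.integers(len(trb_j_pool)))],
                        random_cdr3_nt(rng, int(rng.integers(10, 21))),
                    ),
                }
            else:
                vh = sorted(ref_v["IGH"])[int(rng.integers(len(ref_v["IGH"])))]
                jh = sorted(ref_j["IGH"])[int(rng.integers(len(ref_j["IGH"])))]
                vk = sorted(ref_v["IGK"])[int(rng.integers(len(ref_v["IGK"])))]
                jk = sorted(ref_j["IGK"])[int(rng.integers(len(ref_j["IGK"])))]
                clone.receptor = {
                    "IGH": (vh, jh, random_cdr3_nt(rng, int(rng.integers(10, 21)))),
                    "IGK": (vk, jk, random_cdr3_nt(rng, int(rng.integers(10, 21)))),
                }
            clones[cid] = clone

    # shared clone pools between configured subset pairs (within donor+tissue)
    shared = getattr(config, "shared_clone_pairs", None) or {}
    if shared:
        by_key: dict[tuple, dict[str, list[_Clone]]] = {}
        for clone in clones.values():
            for tissue in clone.members:
                by_key.setdefault((clone.donor, tissue, clone.lineage), {}).setdefault(
                    clone.subset, []
                ).append(clone)
        for (sub_a, sub_b), frac in shared.items():
            for key, by_subset in by_key.items():
                hosts = [c for c in by_subset.get(sub_a, []) if c.size >= 2]
                guests = [c for c in by_subset.get(sub_b, []) if c.size >= 2]
                if not hosts:
                    continue
                for guest in guests:
                    if rng.random() >= frac:
                        continue
                    host = hosts[int(rng.integers(len(hosts)))]
                    for tissue, members in guest.members.items():
                        host.members.setdefault(tissue, []).extend(members)
                    del clones[guest.clone_id]
    return clones


def _apply_trafficking(config, cells, clones, rng) -> None:
    """Re-emit a fraction of expanded single-tissue clones in the other tissue."""
    if config.trafficking_frac <= 0:
        return
    recovered = cells[cells["_recovered"]]
    both = recovered.groupby("donor_id")["tissue"].nunique()
    paired_donors = set(both[both == 2].index)
    # singleton-clone cells of the same subset are the donor pool for
    # cross-tissue re-emission; same-subset keeps per-subset expansion
    # fractions at their configured values
    singleton_pool: dict[tuple, list] = {}
    for clone in clones.values():
        if clone.size == 1:
            tissue = next(iter(clone.tissues))
            (cid,) = clone.members[tissue]
            singleton_pool.setdefault(
                (clone.donor, tissue, clone.subset), []
            ).append(clone.clone_id)
    for key in singleton_pool:
        singleton_pool[key].sort()
    for clone_id in sorted(list(clones)):
        clone = clones.get(clone_id)
        if clone is None or clone.donor not in paired_donors:
            continue
        if clone.size < 2 or len(clone.tissues) != 1:
            continue
        if rng.random() >= config.trafficking_frac:
            continue
        source = next(iter(clone.tissues))
        target = "PBL" if source == "SYN" else "SYN"
        pool = singleton_pool.get((clone.donor, target, clone.subset), [])
        n_move = min(int(rng.integers(1, 3)), len(pool))
        for _ in range(n_move):
            victim_id = pool.pop(int(rng.integers(len(pool))))
            victim = clones.pop(victim_id)
            (moved_cell,) = victim.members[target]
            clone.members.setdefault(target, []).append(moved_cell)


def _plant_viral_matches(config, clones, reference, donor_hla, truth, rng) -> None:
    n_plant = config.viral_plant[1]
    if n_plant <= 0:
        return
    candidates = sorted(
        cid for cid, c in clones.items() if c.lineage == "T" and c.subset.startswith("CD8")
    )
    rng.shuffle(candidates)
    used_rows: set[int] = set()
    planted = 0
    for cid in candidates:
        if planted >= n_plant:
            break
        clone = clones[cid]
        carried = set(donor_hla[clone.donor])
        rows = [
            i
            for i in reference.index
            if reference.at[i, "mhc_allele"] in carried and i not in used_rows
        ]
        if not rows:
            continue
        row = rows[int(rng.integers(len(rows)))]
        used_rows.add(row)
        v, j, _ = clone.receptor["TRB"]
        clone.receptor["TRB"] = (v, j, _backtranslate(reference.at[row, "cdr3b_aa"]))
        truth.viral_clones.append(cid)
        planted += 1
    for cid in truth.viral_clones:
        for members in clones[cid].members.values():
            truth.viral_cells.extend(members)


def _emit_chains(config, cells, clones, switch_offsets, shm_offsets, truth, rng):
    """One contig row per chain per recovered cell, in both table dialects."""
    ref_v = germline.reference_segments("IGH", "V")
    ref_j = germline.reference_segments("IGH", "J")
    subset_of = dict(zip(cells["cell_id"], cells["subset"]))
    contig_rows = []
    airr_rows = []
    n_contigs: dict[str, int] = {}
    aa_cache: dict[str, str] = {}

    def emit(cell_id, locus, v, j, cdr3_nt, c_gene, umis, sequence=""):
        if cdr3_nt not in aa_cache:
            aa_cache[cdr3_nt] = translate_nt(cdr3_nt)
        aa = aa_cache[cdr3_nt]
        n_contigs[cell_id] = n_contigs.get(cell_id, 0) + 1
        contig_id = f"{cell_id}_contig_{n_contigs[cell_id]}"
        reads = int(umis) * int(rng.integers(20, 60))
        contig_rows.append(
            {
                "barcode": cell_id,
                "contig_id": contig_id,
                "chain": locus,
                "v_gene": v,
                "j_gene": j,
                "c_gene": c_gene,
                "cdr3": aa,
                "cdr3_nt": cdr3_nt,
                "umis": int(umis),
                "reads": reads,
                "high_confidence": True,
                "full_length": True,
                "productive": True,
            }
        )
        airr_rows.append(
            {
                "cell_id": cell_id,
                "sequence_id": contig_id,
                "locus": locus,
                "v_call": v,
                "j_call": j,
                "c_call": c_gene,
                "junction": cdr3_nt,
                "junction_aa": aa,
                "duplicate_count": int(umis),
                "consensus_count": reads,
                "productive": "T",
                "sequence": sequence,
            }
        )

    for clone_id in sorted(clones):
        clone = clones[clone_id]
        donor = clone.donor
        for tissue in sorted(clone.members):
            for cell_id in clone.members[tissue]:
                subset = subset_of[cell_id]
                if clone.lineage == "T":
                    va, ja, cdr3a = clone.receptor["TRA"]
                    vb, jb, cdr3b = clone.receptor["TRB"]
                    emit(cell_id, "TRA", va, ja, cdr3a, "TRAC", rng.integers(1, 15))
                    emit(cell_id, "TRB", vb, jb, cdr3b, "TRBC1", rng.integers(5, 40))
                else:
                    vh, jh, cdr3h = clone.receptor["IGH"]
                    vk, jk, cdr3k = clone.receptor["IGK"]
                    rate = config.shm_rate.get(subset, 0.0) + shm_offsets.get(donor, 0.0)
                    if subset.startswith("B") and tissue == "SYN":
                        rate += getattr(config, "shm_tissue_delta", 0.0)
                    rate = min(max(rate, 0.0), 1.0)
                    v_seq = np.array(list(ref_v[vh]))
                    j_seq = np.array(list(ref_j[jh]))
                    v_hit = np.flatnonzero(rng.random(len(v_seq)) < rate)
                    j_hit = np.flatnonzero(rng.random(len(j_seq)) < rate)
                    for arr, hits in ((v_seq, v_hit), (j_seq, j_hit)):
                        for pos in hits:
                            options = [b for b in "ACGT" if b != arr[pos]]
                            arr[pos] = options[int(rng.integers(3))]
                    sequence = "".join(v_seq) + cdr3h + "".join(j_seq)
                    p = config.switch_prob.get(subset, 0.0)
                    if tissue == "SYN":
                        p_logit_shift = getattr(config, "switch_tissue_logit", 0.0)
                    else:
                        p_logit_shift = 0.0
                    if 0.0 < p < 1.0:
                        p = _sigmoid(_logit(p) + switch_offsets[donor] + p_logit_shift)
                    if rng.random() < p:
                        isotype = "IgG" if rng.random() < 0.7 else "IgA"
                    else:
                        isotype = "IgM" if rng.random() < 0.8 else "IgD"
                    c_gene = {
                        "IgG": "IGHG1",
                        "IgA": "IGHA1",
                        "IgM": "IGHM",
                        "IgD": "IGHD",
                    }[isotype]
                    emit(cell_id, "IGH", vh, jh, cdr3h, c_gene, rng.integers(4, 40), sequence)
                    emit(cell_id, "IGK", vk, jk, cdr3k, "IGKC", rng.integers(2, 30))
                    truth.isotype_of[cell_id] = isotype
                    truth.germline_of[cell_id] = (vh, jh, v_hit.tolist(), j_hit.tolist())
    contigs = pd.DataFrame(contig_rows)
    airr = pd.DataFrame(airr_rows)
    return contigs, airr


def _make_expression(config, cells, truth, rng):
    n_genes, n_sig, effect, noise_sd = config.expression
    gene_names = [f"SIG{i:03d}" for i in range(n_sig)] + [
        f"GENE{i:04d}" for i in range(n_genes - n_sig)
    ]
    base = np.empty(n_genes)
    base[:n_sig] = np.log(50.0)
    base[n_sig:] = rng.uniform(np.log(5.0), np.log(40.0), size=n_genes - n_sig)
    n_cells = len(cells)
    affected = (
        cells["subset"].eq(config.signature_subset).to_numpy()
        & cells["cell_id"].map(lambda c: truth.expanded.get(c, False)).to_numpy()
    )
    log_mu = base[None, :] + rng.normal(0.0, noise_sd, size=(n_cells, n_genes))
    log_mu[np.ix_(affected, np.arange(n_sig))] += effect
    counts = rng.poisson(np.exp(log_mu)).astype(np.int64)
    return sparse.csr_matrix(counts.T), gene_names  # genes x cells


def _realized_params(config, cells, truth) -> dict:
    params: dict = {"switch_frac": {}, "mean_clone_size": {}}
    if truth.isotype_of:
        iso = pd.Series(truth.isotype_of)
        sub = cells.set_index("cell_id").loc[iso.index, "subset"]
        switched = iso.isin(["IgG", "IgA"])
        params["switch_frac"] = switched.groupby(sub).mean().to_dict()
    return params


# ---------------------------------------------------------------------------
# fixture writing

FIXTURE_FILES = {
    "cells": "cells.csv",
    "contigs": "filtered_contig_annotations.csv",
    "airr": "airr_rearrangements.tsv",
    "matrix": "matrix.mtx",
    "genes": "genes.tsv",
    "barcodes": "barcodes.tsv",
    "germline": "germline.fasta",
    "hla": "hla.csv",
    "viral": "viral_reference.csv",
    "genesets": "genesets.gmt",
    "config": "config.json",
}


def write_fixture(outdir, config: CohortConfig) -> Cohort:
    """Generate a cohort and write every artifact to ``outdir`` as plain text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    cohort.cells.to_csv(outdir / FIXTURE_FILES["cells"], index=False)
    if len(cohort.contigs):
        cohort.contigs.to_csv(outdir / FIXTURE_FILES["contigs"], index=False)
        cohort.airr.to_csv(outdir / FIXTURE_FILES["airr"], sep="\t", index=False)
    if cohort.counts is not None:
        spio.mmwrite(outdir / FIXTURE_FILES["matrix"], cohort.counts, field="integer")
        pd.Series(cohort.gene_names).to_csv(
            outdir / FIXTURE_FILES["genes"], index=False, header=False
        )
        cohort.cells["cell_id"].to_csv(
            outdir / FIXTURE_FILES["barcodes"], index=False, header=False
        )
        n_sig = config.expression[1]
        sig = [g for g in cohort.gene_names[:n_sig]]
        with open(outdir / FIXTURE_FILES["genesets"], "w") as fh:
            fh.write("planted_signature\tgenerator\t" + "\t".join(sig) + "\n")
    with open(outdir / FIXTURE_FILES["germline"], "w") as fh:
        fh.write(cohort.germline_fasta)
    cohort.hla.to_csv(outdir / FIXTURE_FILES["hla"], index=False)
    cohort.viral_reference.to_csv(outdir / FIXTURE_FILES["viral"], index=False)
    cfg = config.to_dict()
    shared = cfg.pop("shared_clone_pairs", None)
    if shared:
        cfg["shared_clone_pairs"] = {f"{a}|{b}": v for (a, b), v in shared.items()}
    with open(outdir / FIXTURE_FILES["config"], "w") as fh:
        json.dump(cfg, fh, indent=1, default=str)
    return cohort
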