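"""End-to-end orchestration: ingest -> clonotype -> downstream stages.

All intermediates are plain TSV files in the run directory; every table gets
a ``# config_hash=...`` header line so a run is traceable to its exact
configuration.  Reruns with the same config and inputs are bit-identical
for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import analytics, clonotyping, germline, ingest, lineage, shm, signatures, specificity
from .simulate import FIXTURE_FILES

log = logging.getLogger("clonolink")

ALL_STAGES = ("ingest", "clonotype", "stats", "shm", "models", "specificity",
              "score", "lineage")


@dataclass
class RunConfig:
    input_dir: str = "."
    out_dir: str = "run"
    dialect: str = "airr_tsv"
    min_reads: int = 1000
    min_genes: int = 500
    max_mito: float = 0.20
    bcr_threshold: float = 0.965
    identity_denominator: str = "longer"
    reference_subset: str = "B-naive"
    reference_tissue: str = "PBL"
    motif_k: int = 3
    motif_p_cut: float = 0.01
    n_bins: int = 24
    n_ctrl: int = 100
    min_lineage_size: int = 3
    seed: int = 0
    stages: tuple = field(default_factory=lambda: ALL_STAGES)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("input_dir", "out_dir")}  # paths don't alter results
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        cfg = cls()
        for k, v in (data or {}).items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            setattr(cfg, k, tuple(v) if k == "stages" else v)
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write(df: pd.DataFrame, path: Path, cfg: RunConfig, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def run_ingest(cfg: RunConfig, out: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    indir = Path(cfg.input_dir)
    cells = ingest.read_cells(indir / FIXTURE_FILES["cells"])
    contig_file = (
        indir / FIXTURE_FILES["airr"]
        if cfg.dialect == "airr_tsv"
        else indir / FIXTURE_FILES["contigs"]
    )
    chains = ingest.read_contigs(contig_file, cfg.dialect)
    chains = ingest.filter_tcr_chains(chains)
    chains = ingest.filter_bcr_chains(chains)
    cells = ingest.flag_cross_lineage_doublets(cells, chains)
    cells, removal_log = ingest.apply_cell_qc(
        cells, cfg.min_reads, cfg.min_genes, cfg.max_mito
    )
    chains = chains[chains["cell_id"].isin(cells["cell_id"])]
    recovery = ingest.receptor_recovery(cells, chains).rename("recovery").reset_index()
    _write(cells, out / "cells_qc.tsv", cfg)
    _write(chains, out / "chains_qc.tsv", cfg)
    _write(recovery, out / "recovery.tsv", cfg)
    _write(removal_log, out / "qc_removals.tsv", cfg)
    return cells, chains


def run_clonotype(cfg, out, cells, chains):
    tcr = clonotyping.call_tcr_clones(cells, chains)
    bcr = clonotyping.call_bcr_clones(cells, chains, cfg.bcr_threshold,
                                      cfg.identity_denominator)
    _write(tcr.to_frame(), out / "clones_tcr.tsv", cfg)
    _write(bcr.to_frame(), out / "clones_bcr.tsv", cfg)
    mait = clonotyping.flag_invariant_mait(chains)
    _write(mait.reset_index().rename(columns={"index": "cell_id"}),
           out / "mait_flags.tsv", cfg)
    return tcr, bcr


def run_stats(cfg, out, cells, chains, tcr, bcr):
    rows = []
    for lineage_label, table in (("T", tcr), ("B", bcr)):
        pool = cells[cells["lineage"] == lineage_label]
        for subset in sorted(pool["subset"].unique()):
            res = analytics.paired_abundance_test(cells, subset, lineage_label)
            exp = analytics.expansion_fraction(cells, table, subset, tissue="SYN")
            rows.append({
                "subset": subset, "lineage": lineage_label,
                "mean_difference": res.mean_difference,
                "t_statistic": res.statistic, "p_value": res.p_value,
                "syn_expansion_mean": exp["mean"],
            })
    _write(pd.DataFrame(rows), out / "abundance_expansion.tsv", cfg)
    for label, table in (("tcr", tcr), ("bcr", bcr)):
        for tissue in ("SYN", "PBL"):
            mat = analytics.overlap_matrix(table, cells, stratum=tissue)
            _write(mat, out / f"overlap_{label}_{tissue}.tsv", cfg, index=True)
        top = analytics.top_clone_composition(table, cells, n=50, stratum="SYN")
        _write(top, out / f"top_clones_{label}_SYN.tsv", cfg)
        traffic = analytics.trafficking_summary(table, cells)
        _write(traffic, out / f"trafficking_{label}.tsv", cfg)


def run_shm_stage(cfg, out, cells, chains):
    ref = germline.load_reference_fasta(Path(cfg.input_dir) / FIXTURE_FILES["germline"])
    igh = chains[chains["locus"] == "IGH"]
    records = shm.assign_germline(igh, ref)
    switches = shm.classify_switch(igh)
    _write(records, out / "shm_records.tsv", cfg)
    _write(switches, out / "switch_states.tsv", cfg)
    return records, switches


def run_models(cfg, out, cells, records, switches):
    shm_tab = shm.fit_shm_model(records, cells, cfg.reference_subset)
    _write(shm_tab, out / "model_shm.tsv", cfg)
    switch_tab = shm.fit_switch_model(switches, cells, cfg.reference_subset,
                                      cfg.reference_tissue)
    _write(switch_tab, out / "model_switch.tsv", cfg)


def run_specificity(cfg, out, cells, chains, tcr):
    indir = Path(cfg.input_dir)
    reference = pd.read_csv(indir / FIXTURE_FILES["viral"])
    hla = pd.read_csv(indir / FIXTURE_FILES["hla"])
    if reference.empty:
        log.info("specificity: empty viral reference, skipping")
        return
    cd8 = cells[cells["subset"].str.startswith("CD8")]
    cd8_chains = chains[chains["cell_id"].isin(cd8["cell_id"])]
    exact = specificity.exact_match(cd8_chains, reference, cells, hla)
    _write(exact, out / "viral_exact_matches.tsv", cfg)
    clone_of = tcr.clone_of()
    trb = cd8_chains[cd8_chains["locus"] == "TRB"]
    trb = trb[trb["cell_id"].isin(clone_of.index)].copy()
    trb["clone_id"] = clone_of.loc[trb["cell_id"]].to_numpy()
    trb["donor_id"] = trb["cell_id"].map(dict(zip(cells["cell_id"], cells["donor_id"])))
    sample_clones = (trb.groupby("clone_id").first().reset_index()
                     [["clone_id", "donor_id", "cdr3_aa"]]
                     .rename(columns={"cdr3_aa": "cdr3b_aa"}))
    naive = cells[cells["subset"] == "CD8-naive"]
    background = chains[(chains["locus"] == "TRB")
                        & chains["cell_id"].isin(naive["cell_id"])]["cdr3_aa"]
    background = sorted(set(background.astype(str)))
    if not background:
        log.info("specificity: no background clones, skipping motif stage")
        return
    groups, flags = specificity.motif_match(sample_clones, reference, background, hla,
                                            k=cfg.motif_k, p_cut=cfg.motif_p_cut)
    retained = pd.DataFrame([
        {"motif": g.motif, "virus": g.virus, "fisher_p": g.fisher_p,
         "n_reference": len(g.reference_members), "n_sample": len(g.sample_members),
         "hla_restriction": g.hla_restriction}
        for g in groups if g.retained
    ])
    _write(retained, out / "viral_motif_groups.tsv", cfg)
    _write(flags, out / "viral_motif_clone_flags.tsv", cfg)


def run_score(cfg, out, cells, tcr):
    from scipy import io as spio

    indir = Path(cfg.input_dir)
    mtx = indir / FIXTURE_FILES["matrix"]
    gmt = indir / FIXTURE_FILES["genesets"]
    if not mtx.exists() or not gmt.exists():
        log.info("score: no expression matrix / gene sets, skipping")
        return
    counts = spio.mmread(mtx).tocsr()
    genes = pd.read_csv(indir / FIXTURE_FILES["genes"], header=None)[0].tolist()
    barcodes = pd.read_csv(indir / FIXTURE_FILES["barcodes"], header=None)[0].tolist()
    expr = signatures.log_normalize(counts, genes, barcodes)
    expr = expr.loc[expr.index.isin(cells["cell_id"])]
    rows = []
    for name, gene_set in signatures.read_gmt(gmt).items():
        scores = signatures.module_score(expr, gene_set, cfg.n_bins, cfg.n_ctrl,
                                         seed=cfg.seed)
        _write(scores.rename(name).reset_index(), out / f"scores_{name}.tsv", cfg)
        for subset in sorted(cells.loc[cells["lineage"] == "T", "subset"].unique()):
            res = signatures.expanded_vs_unexpanded(scores, cells, tcr, subset)
            rows.append({"gene_set": name, "subset": subset,
                         "mean_difference": res["mean_difference"],
                         "p_value": res["p_value"], "n_pairs": res["n_pairs"]})
    _write(pd.DataFrame(rows), out / "expanded_vs_unexpanded.tsv", cfg)


def run_lineage(cfg, out, records, bcr):
    trees = lineage.build_clone_trees(records, bcr, min_size=cfg.min_lineage_size)
    tree_dir = out / "lineage_trees"
    tree_dir.mkdir(exist_ok=True)
    for cid, tree in trees.items():
        safe = cid.replace(":", "_").replace("/", "_")
        (tree_dir / f"{safe}.nwk").write_text(tree.newick + "\n")
    log.info("lineage: wrote %d trees", len(trees))


def run_all(cfg: RunConfig) -> Path:
    """Execute the enabled stages in dependency order; returns the run dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.json", "w") as fh:
        json.dump({**asdict(cfg), "config_hash": cfg.config_hash()}, fh, indent=1,
                  default=str)
    state: dict = {}

    def stage(name, fn, *args):
        if name not in cfg.stages:
            log.info("stage %s: skipped", name)
            return None
        log.info("stage %s: running", name)
        try:
            return fn(*args)
        except Exception as exc:  # noqa: BLE001 - aborting with stage context
            raise StageError(name, exc) from exc

    res = stage("ingest", run_ingest, cfg, out)
    if res is None:
        raise StageError("ingest", RuntimeError("ingest stage is required"))
    cells, chains = res
    res = stage("clonotype", run_clonotype, cfg, out, cells, chains)
    if res is not None:
        state["tcr"], state["bcr"] = res
    if "tcr" in state:
        stage("stats", run_stats, cfg, out, cells, chains, state["tcr"], state["bcr"])
        stage("specificity", run_specificity, cfg, out, cells, chains, state["tcr"])
        stage("score", run_score, cfg, out, cells, state["tcr"])
    res = stage("shm", run_shm_stage, cfg, out, cells, chains)
    if res is not None:
        state["records"], state["switches"] = res
        stage("models", run_models, cfg, out, cells, state["records"], state["switches"])
        if "bcr" in state:
            stage("lineage", run_lineage, cfg, out, state["records"], state["bcr"])
    return out
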