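"""Cohort and run configuration objects.

``CohortConfig`` parameterises the synthetic cohort generator; the
``paper_default()`` preset encodes the published cohort-level summary values
(per-tissue subset composition, expansion fractions, isotype-switch
probabilities, receptor recovery rates) so downstream stages can be validated
by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

TISSUES = ("SYN", "PBL")

CD4_SUBSETS = ("CD4-naive", "CD4-Tph", "CD4-Tfh/Tph", "CD4-memory")
CD8_SUBSETS = ("CD8-naive", "CD8-GZMK/B", "CD8-GZMB-TEMRA")
T_SUBSETS = CD4_SUBSETS + CD8_SUBSETS + ("MAIT",)
B_SUBSETS = ("B-naive", "B-memory", "B-activated", "B-ABC", "B-plasma")


class ConfigurationError(ValueError):
    """Raised when a cohort/run configuration is internally inconsistent."""


@dataclass
class CohortConfig:
    """Parameters of one synthetic paired-tissue cohort.

    ``composition`` maps tissue -> subset -> proportion and must sum to 1 per
    tissue within each lineage (T subsets and B subsets separately).
    ``expansion`` maps subset -> (fraction of receptor-bearing cells in clones
    of size >= 2, truncated-geometric continuation probability).
    """

    n_donors: int = 12
    n_blood_donors: int = 10
    cells_per_sample_T: int = 300
    cells_per_sample_B: int = 200
    composition: dict = field(default_factory=dict)
    expansion: dict = field(default_factory=dict)
    shm_rate: dict = field(default_factory=dict)
    switch_prob: dict = field(default_factory=dict)
    recovery_prob: dict = field(default_factory=lambda: {"SYN": 1.0, "PBL": 1.0})
    trafficking_frac: float = 0.0
    shared_clone_pairs: dict = field(default_factory=dict)  # (subsetA, subsetB) -> frac
    switch_tissue_logit: float = 0.0  # extra class-switch log-odds in SYN
    shm_tissue_delta: float = 0.0  # extra per-site SHM rate in SYN
    viral_plant: tuple = (0, 0)  # (n_reference_rows, n_planted_matching_clones)
    expression: tuple | None = None  # (n_genes, n_signature_genes, effect, noise_sd)
    signature_subset: str = "CD4-Tph"
    donor_sd_switch: float = 0.25
    donor_sd_shm: float = 0.0005
    include_receptors: bool = True
    include_expression: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_blood_donors > self.n_donors:
            raise ConfigurationError(
                f"n_blood_donors ({self.n_blood_donors}) exceeds n_donors ({self.n_donors})"
            )
        for tissue, comp in self.composition.items():
            if tissue not in TISSUES:
                raise ConfigurationError(f"unknown tissue {tissue!r}")
            for lineage, members in (("T", T_SUBSETS), ("B", B_SUBSETS)):
                total = sum(p for s, p in comp.items() if s in members)
                if abs(total - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"composition for tissue {tissue}/{lineage} sums to {total}, not 1"
                    )
            for s, p in comp.items():
                if not 0 <= p <= 1:
                    raise ConfigurationError(f"proportion out of [0,1] for {tissue}/{s}")
        for name, table in (
            ("expansion", {k: v[0] for k, v in self.expansion.items()}),
            ("shm_rate", self.shm_rate),
            ("switch_prob", self.switch_prob),
            ("recovery_prob", self.recovery_prob),
        ):
            for k, p in table.items():
                if not 0 <= p <= 1:
                    raise ConfigurationError(f"{name}[{k!r}] = {p} outside [0,1]")
        if not 0 <= self.trafficking_frac <= 1:
            raise ConfigurationError("trafficking_frac outside [0,1]")

    def to_dict(self) -> dict:
        return asdict(self)


def paper_default(seed: int = 0, **overrides) -> CohortConfig:
    """Preset encoding the published cohort-level summary values.

    Composition: naive cells are 45% of blood CD4 vs 5% of synovial CD4,
    and 64.5% of blood B cells vs 9.1% of synovial B cells.  Expansion:
    12.5% of synovial Tph cells sit in expanded TCR clones.  Receptor
    recovery: 84.7% (synovium) and 93.1% (blood).  Switch probabilities:
    0% naive, 40% activated, 65% ABC, 75% memory, ~97% plasma cells.
    Per-subset SHM rates are ordinal (naive < activated/ABC < memory <
    plasma); the source reports them only graphically.
    """
    # T-subset proportions are over all T cells; within-CD4 naive fraction is
    # 0.27/0.60 = 45% (PBL) and 0.03/0.60 = 5% (SYN).
    composition = {
        "PBL": {
            "CD4-naive": 0.27,
            "CD4-Tph": 0.015,
            "CD4-Tfh/Tph": 0.015,
            "CD4-memory": 0.30,
            "CD8-naive": 0.15,
            "CD8-GZMK/B": 0.03,
            "CD8-GZMB-TEMRA": 0.17,
            "MAIT": 0.05,
            "B-naive": 0.645,
            "B-memory": 0.20,
            "B-activated": 0.05,
            "B-ABC": 0.055,
            "B-plasma": 0.05,
        },
        "SYN": {
            "CD4-naive": 0.03,
            "CD4-Tph": 0.12,
            "CD4-Tfh/Tph": 0.09,
            "CD4-memory": 0.36,
            "CD8-naive": 0.04,
            "CD8-GZMK/B": 0.22,
            "CD8-GZMB-TEMRA": 0.06,
            "MAIT": 0.08,
            "B-naive": 0.091,
            "B-memory": 0.15,
            "B-activated": 0.30,
            "B-ABC": 0.209,
            "B-plasma": 0.25,
        },
    }
    expansion = {
        "CD4-naive": (0.0, 0.4),
        "CD4-Tph": (0.125, 0.4),
        "CD4-Tfh/Tph": (0.10, 0.4),
        "CD4-memory": (0.05, 0.4),
        "CD8-naive": (0.0, 0.4),
        "CD8-GZMK/B": (0.50, 0.5),
        "CD8-GZMB-TEMRA": (0.40, 0.5),
        "MAIT": (0.30, 0.4),
        "B-naive": (0.0, 0.4),
        "B-memory": (0.10, 0.4),
        "B-activated": (0.15, 0.4),
        "B-ABC": (0.15, 0.4),
        "B-plasma": (0.40, 0.5),
    }
    shm_rate = {
        "B-naive": 0.001,
        "B-activated": 0.010,
        "B-ABC": 0.012,
        "B-memory": 0.020,
        "B-plasma": 0.030,
    }
    switch_prob = {
        "B-naive": 0.0,
        "B-activated": 0.40,
        "B-ABC": 0.65,
        "B-memory": 0.75,
        "B-plasma": 0.97,
    }
    cfg = CohortConfig(
        n_donors=12,
        n_blood_donors=10,
        composition=composition,
        expansion=expansion,
        shm_rate=shm_rate,
        switch_prob=switch_prob,
        recovery_prob={"SYN": 0.847, "PBL": 0.931},
        trafficking_frac=0.10,
        shared_clone_pairs={("CD4-Tph", "CD4-Tfh/Tph"): 0.6},
        viral_plant=(60, 8),
        expression=(500, 20, 0.5, 0.25),
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def shared_pool_overlap_config(seed: int = 0, **overrides) -> CohortConfig:
    """Small preset used for overlap scenarios and quick tests."""
    cfg = paper_default(seed=seed)
    cfg.n_donors = 4
    cfg.n_blood_donors = 3
    cfg.cells_per_sample_T = 150
    cfg.cells_per_sample_B = 100
    cfg.viral_plant = (20, 3)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg
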