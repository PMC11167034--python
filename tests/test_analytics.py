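import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonolink import analytics
from clonolink.analytics import (
    cdr3_properties,
    expansion_fraction,
    morisita_horn,
    overlap_matrix,
    paired_abundance_test,
    top_clone_composition,
    trafficking_summary,
)
from clonolink.clonotyping import CloneTable, call_tcr_clones

from conftest import make_cells, make_chains


def _qc_chains(cohort):
    import io as _io

    from clonolink import ingest

    buf = _io.StringIO()
    cohort.airr.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    chains = ingest.read_contigs(buf, "airr_tsv")
    return ingest.filter_bcr_chains(ingest.filter_tcr_chains(chains))


def clone_table(mapping):
    return CloneTable(pd.DataFrame(
        [{"cell_id": c, "clone_id": k} for c, k in mapping.items()]
    ))


class TestMorisitaHorn:
    def test_identical_vectors_is_one(self):
        counts = {"c1": 5, "c2": 3}
        assert morisita_horn(counts, counts) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        assert morisita_horn({"a": 4}, {"b": 7}) == 0.0

    def test_worked_two_clone_example(self):
        # independent hand computation: Na=Nb=3, sum(ab)=2+2=4,
        # Da=Db=(4+1)/9=5/9, MH = 2*4 / ((10/9)*3*3) = 8/10 = 0.8
        assert morisita_horn({"c1": 2, "c2": 1}, {"c1": 1, "c2": 2}) == pytest.approx(0.8)

    def test_empty_side_is_missing(self):
        assert morisita_horn({}, {"a": 1}) is None
        assert morisita_horn({"a": 0}, {"a": 1}) is None

    counts_strategy = st.dictionaries(
        st.sampled_from([f"k{i}" for i in range(8)]),
        st.integers(min_value=1, max_value=50),
        min_size=1, max_size=8,
    )

    @given(a=counts_strategy, b=counts_strategy)
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        ab = morisita_horn(a, b)
        ba = morisita_horn(b, a)
        assert ab == pytest.approx(ba)
        assert -1e-12 <= ab <= 1 + 1e-12

    @given(a=counts_strategy, b=counts_strategy,
           scale=st.integers(min_value=2, max_value=9))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariant(self, a, b, scale):
        scaled = {k: v * scale for k, v in a.items()}
        assert morisita_horn(a, b) == pytest.approx(morisita_horn(scaled, b))

    @given(a=counts_strategy, scale=st.integers(min_value=1, max_value=5))
    @settings(max_examples=100, deadline=None)
    def test_proportional_vectors_give_one(self, a, scale):
        scaled = {k: v * scale for k, v in a.items()}
        assert morisita_horn(a, scaled) == pytest.approx(1.0)


class TestOverlapMatrix:
    def _setup(self, subsets_of_clone):
        # two cells per (clone, subset) listing
        cells, mapping = [], {}
        i = 0
        for clone, subsets in subsets_of_clone.items():
            for subset in subsets:
                for _ in range(2):
                    cid = f"c{i}"
                    cells.append({"cell_id": cid, "subset": subset})
                    mapping[cid] = clone
                    i += 1
        return make_cells(cells), clone_table(mapping)

    def test_shared_pool_near_one(self):
        cells, clones = self._setup({"k1": ["A", "B"], "k2": ["A", "B"]})
        mat = overlap_matrix(clones, cells, stratum="SYN")
        assert mat.loc["A", "B"] == pytest.approx(1.0)

    def test_disjoint_pools_zero(self):
        cells, clones = self._setup({"k1": ["A"], "k2": ["B"]})
        mat = overlap_matrix(clones, cells, stratum="SYN")
        assert mat.loc["A", "B"] == 0.0

    def test_diagonal_one_and_symmetric(self, ingested):
        cells, chains = ingested
        clones = call_tcr_clones(cells, chains)
        mat = overlap_matrix(clones, cells, stratum="SYN")
        vals = mat.to_numpy(dtype=float)
        assert np.allclose(vals, vals.T, equal_nan=True)
        diag = np.diag(vals)
        assert np.all((np.isnan(diag)) | (np.abs(diag - 1) < 1e-12))

    def test_planted_tph_tfh_sharing_dominates(self):
        # generator merges a fraction of Tfh/Tph clones into Tph clone pools
        from clonolink import generate_cohort, paper_default

        cfg = paper_default(seed=13, include_expression=False)
        cfg.n_donors, cfg.n_blood_donors = 3, 2
        cfg.cells_per_sample_T, cfg.cells_per_sample_B = 500, 40
        cfg.expansion["CD4-Tph"] = (0.4, 0.4)
        cfg.expansion["CD4-Tfh/Tph"] = (0.4, 0.4)
        cfg.shared_clone_pairs = {("CD4-Tph", "CD4-Tfh/Tph"): 0.8}
        co = generate_cohort(cfg)
        cells = co.cells
        chains = _qc_chains(co)
        clones = call_tcr_clones(cells, chains)
        mat = overlap_matrix(clones, cells, stratum="SYN")
        row = mat.loc["CD4-Tph"].drop("CD4-Tph").fillna(0)
        assert row.idxmax() == "CD4-Tfh/Tph"
        assert row["CD4-Tfh/Tph"] > row.drop("CD4-Tfh/Tph").max()


class TestExpansionFraction:
    def test_all_singletons_zero(self):
        cells = make_cells([{"cell_id": f"c{i}", "subset": "S"} for i in range(3)])
        clones = clone_table({f"c{i}": f"k{i}" for i in range(3)})
        res = expansion_fraction(cells, clones, "S")
        assert res["mean"] == 0.0

    def test_half_expanded(self):
        cells = make_cells([{"cell_id": f"c{i}", "subset": "S"} for i in range(4)])
        clones = clone_table({"c0": "k1", "c1": "k1", "c2": "k2", "c3": "k3"})
        res = expansion_fraction(cells, clones, "S")
        assert res["mean"] == pytest.approx(0.5)

    def test_no_cells_gives_nan(self):
        cells = make_cells([{"cell_id": "c0", "subset": "other"}])
        res = expansion_fraction(cells, clone_table({"c0": "k0"}), "S")
        assert np.isnan(res["mean"])

    def test_monotone_in_threshold(self, ingested):
        cells, chains = ingested
        clones = call_tcr_clones(cells, chains)
        fracs = [expansion_fraction(cells, clones, "CD8-GZMK/B", tissue="SYN",
                                    min_size=m)["mean"] for m in (5, 3, 2, 1)]
        assert fracs == sorted(fracs)
        assert fracs[-1] == pytest.approx(1.0)  # every assigned cell has size >= 1

    def test_generator_tph_recovery(self, ingested, small_cohort):
        cells, chains = ingested
        clones = call_tcr_clones(cells, chains)
        res = expansion_fraction(cells, clones, "CD4-Tph", tissue="SYN")
        planted = small_cohort.config.expansion["CD4-Tph"][0]
        assert abs(res["mean"] - planted) < 0.15  # few Tph cells per donor here


class TestTopCloneComposition:
    def test_returns_all_when_fewer_than_n(self):
        cells = make_cells([{"cell_id": f"c{i}", "subset": "S"} for i in range(6)])
        clones = clone_table({"c0": "k1", "c1": "k1", "c2": "k2", "c3": "k2",
                              "c4": "k3", "c5": "k4"})
        out = top_clone_composition(clones, cells, n=50, stratum="SYN")
        assert len(out) == 4

    def test_cross_tissue_flagged(self):
        cells = make_cells([
            {"cell_id": "c0", "subset": "S"},
            {"cell_id": "c1", "subset": "S"},
            {"cell_id": "c2", "subset": "S", "tissue": "PBL",
             "sample_id": "D01-PBL"},
        ])
        clones = clone_table({"c0": "k1", "c1": "k1", "c2": "k1"})
        out = top_clone_composition(clones, cells, stratum="SYN")
        assert out["shared_other_tissue"].all()
        assert out.loc[0, "size"] == 2  # within-stratum size

    def test_generator_large_syn_clones_dominated_by_gzmkb(self, ingested,
                                                           small_cohort):
        cells, chains = ingested
        clones = call_tcr_clones(cells, chains)
        t_cells = cells[cells["lineage"] == "T"]
        out = top_clone_composition(clones, t_cells, n=20, stratum="SYN")
        subset_cols = [c for c in out.columns
                       if c not in ("clone_id", "size", "shared_other_tissue")]
        totals = out[subset_cols].sum()
        assert totals.idxmax() == "CD8-GZMK/B"


class TestTrafficking:
    def test_no_trafficking_empty(self):
        from clonolink import generate_cohort, paper_default

        cfg = paper_default(seed=31, trafficking_frac=0.0, shared_clone_pairs={},
                            include_expression=False)
        cfg.n_donors, cfg.n_blood_donors = 2, 2
        cfg.cells_per_sample_T = cfg.cells_per_sample_B = 60
        co = generate_cohort(cfg)
        clones = clone_table(co.truth.clone_of)
        assert len(trafficking_summary(clones, co.cells)) == 0

    def test_differing_compositions_reported(self):
        cells = make_cells([
            {"cell_id": "c0", "subset": "B-plasma", "lineage": "B"},
            {"cell_id": "c1", "subset": "B-plasma", "lineage": "B"},
            {"cell_id": "c2", "subset": "B-memory", "lineage": "B",
             "tissue": "PBL", "sample_id": "D01-PBL"},
        ])
        clones = clone_table({"c0": "k1", "c1": "k1", "c2": "k1"})
        out = trafficking_summary(clones, cells)
        syn = out[out["tissue"] == "SYN"].iloc[0]
        pbl = out[out["tissue"] == "PBL"].iloc[0]
        assert syn["B-plasma"] == 2 and syn["size"] == 2
        assert pbl["B-memory"] == 1 and pbl["size"] == 1

    def test_partition_of_clones(self, ingested):
        # shared-clone table plus single-tissue clones covers all clones once
        cells, chains = ingested
        clones = call_tcr_clones(cells, chains)
        out = trafficking_summary(clones, cells)
        shared = set(out["clone_id"])
        merged = cells.merge(clones.assignments, on="cell_id")
        n_tissues = merged.groupby("clone_id")["tissue"].nunique()
        assert shared == set(n_tissues[n_tissues == 2].index)


class TestCdr3Properties:
    def test_worked_example(self):
        # residue-count oracle: R+K=2, D+E=1 -> charge +1, length 6
        out = cdr3_properties(make_chains([
            {"cell_id": "c1", "cdr3_aa": "CARDKW"}]))
        assert out.loc[0, "cdr3_length"] == 6
        assert out.loc[0, "cdr3_charge"] == 1

    def test_no_charged_residues(self):
        out = cdr3_properties(make_chains([
            {"cell_id": "c1", "cdr3_aa": "CASSGW"}]))
        assert out.loc[0, "cdr3_charge"] == 0

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError, match="empty CDR3"):
            cdr3_properties(make_chains([{"cell_id": "c1", "cdr3_aa": ""}]))

    def test_nonstandard_residue_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="non-standard"):
            out = cdr3_properties(make_chains([
                {"cell_id": "c1", "cdr3_aa": "CAXSW"}]))
        assert np.isnan(out.loc[0, "cdr3_charge"])
        assert out.loc[0, "cdr3_length"] == 5


class TestPairedAbundance:
    def _cells(self, fractions):
        # fractions: donor -> (syn_frac, pbl_frac) of subset "S" among 10 cells
        rows = []
        for donor, (syn, pbl) in fractions.items():
            for tissue, frac in (("SYN", syn), ("PBL", pbl)):
                for i in range(10):
                    rows.append({
                        "cell_id": f"{donor}-{tissue}-{i}", "donor_id": donor,
                        "sample_id": f"{donor}-{tissue}", "tissue": tissue,
                        "subset": "S" if i < frac * 10 else "other",
                    })
        return make_cells(rows)

    def test_identical_fractions_give_t0_p1(self):
        cells = self._cells({"D01": (0.3, 0.3), "D02": (0.5, 0.5),
                             "D03": (0.2, 0.2)})
        res = paired_abundance_test(cells, "S")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_single_pair_missing_p(self):
        cells = self._cells({"D01": (0.4, 0.2)})
        res = paired_abundance_test(cells, "S")
        assert np.isnan(res.p_value)

    def test_strong_effect_detected(self):
        cells = self._cells({f"D{i:02d}": (0.8, 0.2) for i in range(1, 7)})
        res = paired_abundance_test(cells, "S")
        assert res.p_value < 0.01
        assert res.mean_difference == pytest.approx(0.6)

    def test_wilcoxon_variant(self):
        cells = self._cells({f"D{i:02d}": (0.8, 0.2) for i in range(1, 7)})
        res = paired_abundance_test(cells, "S", method="wilcoxon")
        assert res.p_value < 0.05

    def test_holm_correction_monotone(self):
        p = pd.Series([0.01, 0.04, 0.3, np.nan], index=list("abcd"))
        adj = analytics.holm_correction(p)
        assert adj["a"] == pytest.approx(0.03)
        assert np.isnan(adj["d"])
        assert (adj.dropna() >= p.dropna()).all()
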