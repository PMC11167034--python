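import numpy as np
import pandas as pd
import pytest

from clonolink.clonotyping import (
    CloneTable,
    call_bcr_clones,
    call_tcr_clones,
    categorize_clone_sizes,
    cdr3_identity,
    flag_invariant_mait,
    greedy_cluster,
    size_category,
)
from clonolink.config import ConfigurationError

from conftest import make_cells, make_chains


# ---------------------------------------------------------------------------
# independent oracle: brute-force all-pairs single-linkage at an identity
# threshold (union-find), sharing nothing with the greedy implementation

def _pair_identity(a: str, b: str) -> float:
    if len(a) < len(b):
        a, b = b, a
    best = 0
    for off in range(len(a) - len(b) + 1):
        best = max(best, sum(x == y for x, y in zip(a[off:], b)))
    return best / len(a)


def single_linkage_oracle(seqs, threshold):
    parent = list(range(len(seqs)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if _pair_identity(seqs[i], seqs[j]) >= threshold:
                parent[find(i)] = find(j)
    return [find(i) for i in range(len(seqs))]


def _mutate(rng, seq, n_subs):
    arr = list(seq)
    for pos in rng.choice(len(arr), size=n_subs, replace=False):
        arr[pos] = rng.choice([b for b in "ACGT" if b != arr[pos]])
    return "".join(arr)


def random_cdr3_families(rng, n_families=40, max_members=5, length_range=(30, 60)):
    seqs = []
    for _ in range(n_families):
        length = rng.choice(np.arange(length_range[0], length_range[1] + 1, 3))
        base = "".join(rng.choice(list("ACGT"), size=length))
        seqs.append(base)
        for _ in range(int(rng.integers(0, max_members))):
            seqs.append(_mutate(rng, base, int(rng.integers(0, 3))))
    return seqs


class TestCdr3Identity:
    def test_one_mismatch_of_30(self):
        a = "A" * 30
        b = "A" * 15 + "C" + "A" * 14
        assert cdr3_identity(a, b) == pytest.approx(29 / 30)

    def test_two_mismatches_of_30(self):
        a = "A" * 30
        b = "C" + "A" * 28 + "C"
        assert cdr3_identity(a, b) == pytest.approx(28 / 30)

    def test_identical(self):
        assert cdr3_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_length_mismatch_denominator(self):
        a = "ACGTACGTACGT"  # 12
        b = "ACGTACGT"  # 8, exact prefix
        assert cdr3_identity(a, b, "longer") == pytest.approx(8 / 12)
        assert cdr3_identity(a, b, "shorter") == pytest.approx(1.0)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(15, 40))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(15, 40))))
            assert cdr3_identity(a, b) == cdr3_identity(b, a)


class TestCallTcrClones:
    def _cells(self):
        return make_cells([
            {"cell_id": "c1"}, {"cell_id": "c2"},
            {"cell_id": "c3", "donor_id": "D02", "sample_id": "D02-SYN"},
            {"cell_id": "c4"}, {"cell_id": "c5"},
        ])

    def test_identical_pair_one_clone(self):
        chains = make_chains([
            {"cell_id": "c1", "locus": "TRA", "cdr3_nt": "TGTGCAGTG"},
            {"cell_id": "c1", "locus": "TRB", "cdr3_nt": "TGTGCAAGC"},
            {"cell_id": "c2", "locus": "TRA", "cdr3_nt": "TGTGCAGTG"},
            {"cell_id": "c2", "locus": "TRB", "cdr3_nt": "TGTGCAAGC"},
        ])
        table = call_tcr_clones(self._cells(), chains)
        assert table.assignments["clone_id"].nunique() == 1
        assert table.sizes.iloc[0] == 2
        assert table.size_categories.iloc[0] == "small"

    def test_same_key_different_donor_distinct(self):
        chains = make_chains([
            {"cell_id": "c1", "locus": "TRB", "cdr3_nt": "TGTGCAAGC"},
            {"cell_id": "c1", "locus": "TRA", "cdr3_nt": "TGTGCAGTG"},
            {"cell_id": "c3", "locus": "TRB", "cdr3_nt": "TGTGCAAGC"},
            {"cell_id": "c3", "locus": "TRA", "cdr3_nt": "TGTGCAGTG"},
        ])
        table = call_tcr_clones(self._cells(), chains)
        assert table.assignments["clone_id"].nunique() == 2

    def test_same_cdr3_different_v_distinct(self):
        # key-equality oracle: keys differing in any field must split clones
        chains = make_chains([
            {"cell_id": "c1", "locus": "TRB", "v_call": "TRBV2", "cdr3_nt": "TGTGCAAGC"},
            {"cell_id": "c1", "locus": "TRA", "cdr3_nt": "TGTGCAGTG"},
            {"cell_id": "c2", "locus": "TRB", "v_call": "TRBV9", "cdr3_nt": "TGTGCAAGC"},
            {"cell_id": "c2", "locus": "TRA", "cdr3_nt": "TGTGCAGTG"},
        ])
        table = call_tcr_clones(self._cells(), chains)
        assert table.assignments["clone_id"].nunique() == 2

    def test_doublet_cells_excluded(self):
        cells = self._cells()
        cells.loc[cells["cell_id"] == "c1", "doublet_flag"] = True
        chains = make_chains([
            {"cell_id": "c1", "locus": "TRA"}, {"cell_id": "c1", "locus": "TRB"},
        ])
        table = call_tcr_clones(cells, chains)
        assert len(table.assignments) == 0

    def test_ground_truth_recovery(self, ingested, small_cohort):
        from sklearn.metrics import adjusted_rand_score

        cells, chains = ingested
        table = call_tcr_clones(cells, chains)
        truth = pd.Series(small_cohort.truth.clone_of)
        called = table.clone_of()
        common = called.index.intersection(truth.index)
        assert adjusted_rand_score(truth.loc[common], called.loc[common]) >= 0.99


class TestCallBcrClones:
    def _run(self, cdr3s, threshold=0.965):
        cells = make_cells([{"cell_id": f"c{i}", "lineage": "B",
                             "subset": "B-memory"} for i in range(len(cdr3s))])
        chains = make_chains([
            {"cell_id": f"c{i}", "locus": "IGH", "cdr3_nt": s,
             "cdr3_aa": "X" * (len(s) // 3)}
            for i, s in enumerate(cdr3s)
        ])
        return call_bcr_clones(cells, chains, threshold)

    def test_one_mismatch_same_clone_at_965(self):
        a = "ACGT" * 7 + "AC"  # 30 nt
        b = a[:10] + ("C" if a[10] != "C" else "G") + a[11:]
        table = self._run([a, b])
        assert table.assignments["clone_id"].nunique() == 1

    def test_two_mismatches_split_at_965_join_at_80(self):
        a = "ACGT" * 7 + "AC"
        b = "T" + a[1:-1] + "G"
        assert self._run([a, b], 0.965).assignments["clone_id"].nunique() == 2
        assert self._run([a, b], 0.80).assignments["clone_id"].nunique() == 1

    def test_identical_sequences_always_merge(self):
        a = "ACGTACGTACGTACGTACGTACGTACGTAC"
        for thr in (0.5, 0.8, 0.965, 1.0):
            assert self._run([a, a, a], thr).assignments["clone_id"].nunique() == 1

    def test_bad_threshold(self):
        with pytest.raises(ConfigurationError):
            self._run(["ACGTACGTACGTACG"], threshold=1.5)

    def test_greedy_matches_single_linkage_on_families(self):
        rng = np.random.default_rng(42)
        for rep in range(5):
            seqs = random_cdr3_families(rng)
            uniq = sorted(set(seqs), key=seqs.index)
            counts = [seqs.count(s) for s in uniq]
            for threshold in (0.965, 0.80):
                label = greedy_cluster(uniq, counts, threshold)
                oracle = single_linkage_oracle(uniq, threshold)
                greedy_part = pd.Series([label[s] for s in uniq])
                oracle_part = pd.Series(oracle)
                same = (
                    greedy_part.groupby(oracle_part).nunique().eq(1).all()
                    and oracle_part.groupby(greedy_part).nunique().eq(1).all()
                )
                if not same:
                    # fallback guarantee: every member is within threshold of
                    # its cluster representative
                    reps = {}
                    for s in uniq:
                        reps.setdefault(label[s], s)
                    for s in uniq:
                        assert cdr3_identity(s, reps[label[s]]) >= threshold

    def test_lower_threshold_never_more_clones(self):
        rng = np.random.default_rng(7)
        seqs = sorted(set(random_cdr3_families(rng)))
        counts = [1] * len(seqs)
        n_clones = [
            len(set(greedy_cluster(seqs, counts, t).values()))
            for t in (1.0, 0.965, 0.9, 0.8, 0.5)
        ]
        assert n_clones == sorted(n_clones, reverse=True)

    def test_ground_truth_recovery(self, ingested, small_cohort):
        from sklearn.metrics import adjusted_rand_score

        cells, chains = ingested
        table = call_bcr_clones(cells, chains)
        truth = pd.Series(small_cohort.truth.clone_of)
        called = table.clone_of()
        common = called.index.intersection(truth.index)
        assert adjusted_rand_score(truth.loc[common], called.loc[common]) >= 0.95


class TestSizeCategories:
    @pytest.mark.parametrize("size,expected", [
        (1, "singleton"), (2, "small"), (3, "small"), (5, "small"),
        (6, "medium"), (19, "medium"), (20, "large"), (50, "large"),
        (100, "large"), (101, "hyperexpanded"), (500, "hyperexpanded"),
    ])
    def test_bins(self, size, expected):
        assert size_category(size) == expected

    def test_categorize_table(self):
        assignments = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(4)],
            "clone_id": ["k1", "k1", "k1", "k2"],
        })
        out = categorize_clone_sizes(CloneTable(assignments))
        by = out.set_index("clone_id")
        assert by.loc["k1", "size_category"] == "small"
        assert by.loc["k2", "size_category"] == "singleton"


class TestMaitFlag:
    @pytest.mark.parametrize("v,j,expected", [
        ("TRAV1-2", "TRAJ33", True),
        ("TRAV1-2", "TRAJ20", True),
        ("TRAV1-2", "TRAJ12", True),
        ("TRAV1-2", "TRAJ42", False),
        ("TRAV12-1", "TRAJ33", False),
        ("TRAV1-2*01", "TRAJ33*01", True),  # allele suffixes stripped
    ])
    def test_flag(self, v, j, expected):
        chains = make_chains([
            {"cell_id": "c1", "locus": "TRA", "v_call": v, "j_call": j},
            {"cell_id": "c1", "locus": "TRB"},
        ])
        flags = flag_invariant_mait(chains)
        assert flags["c1"] == expected

    def test_trb_ignored(self):
        chains = make_chains([
            {"cell_id": "c1", "locus": "TRB", "v_call": "TRAV1-2",
             "j_call": "TRAJ33"},
        ])
        assert not flag_invariant_mait(chains)["c1"]

    def test_generator_mait_detected(self, ingested, small_cohort):
        cells, chains = ingested
        flags = flag_invariant_mait(chains)
        mait = cells[cells["subset"] == "MAIT"]
        with_tcr = mait[mait["cell_id"].isin(flags.index)]
        assert flags.loc[with_tcr["cell_id"]].mean() > 0.5
        non_mait = cells[(cells["lineage"] == "T") & (cells["subset"] != "MAIT")]
        non_mait = non_mait[non_mait["cell_id"].isin(flags.index)]
        assert flags.loc[non_mait["cell_id"]].mean() == 0.0
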