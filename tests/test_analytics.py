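"""Repertoire sharing statistics, clustering, and randomization tests."""

import numpy as np
import pandas as pd
import pytest

from tcrseek.analytics import (
    Repertoire,
    cluster_cdr3,
    clusters_to_frame,
    overlap_summary,
    pair_cooccurrence_test,
    pmhc_sharing_test,
    sequence_identity,
    sharing_profile,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _rep(ind, tissue, alphas=(), betas=(), counts=None):
    rows = []
    for chain, seqs in (("alpha", alphas), ("beta", betas)):
        for i, aa in enumerate(seqs):
            rows.append(
                {
                    "chain": chain, "cdr3_nt": "NNN", "cdr3_aa": aa,
                    "read_count": (counts or {}).get(aa, 1),
                }
            )
    df = pd.DataFrame(rows, columns=["chain", "cdr3_nt", "cdr3_aa", "read_count"])
    return Repertoire(individual_id=ind, tissue_label=tissue, df=df)


class TestOverlap:
    def test_disjoint_sets(self):
        pairs = [(
            _rep("p1", "tumor", betas=("CASA", "CASB", "CASC")),
            _rep("p1", "normal", betas=("CASD", "CASE")),
        )]
        summary, per_cdr3 = overlap_summary(pairs)
        row = summary.set_index("chain").loc["beta"]
        assert (row.tumor_only, row.normal_only, row.shared) == (3, 2, 0)
        assert len(per_cdr3) == 5

    def test_identical_sets(self):
        pairs = [(
            _rep("p1", "tumor", betas=("CASA", "CASB")),
            _rep("p1", "normal", betas=("CASA", "CASB")),
        )]
        summary, _ = overlap_summary(pairs)
        row = summary.set_index("chain").loc["beta"]
        assert (row.tumor_only, row.normal_only, row.shared) == (0, 0, 2)

    def test_partition_conservation(self):
        pairs = [
            (_rep("p1", "tumor", betas=("CASA", "CASB")),
             _rep("p1", "normal", betas=("CASB",))),
            (_rep("p2", "tumor", betas=("CASC",)),
             _rep("p2", "normal", betas=("CASD",))),
        ]
        summary, per_cdr3 = overlap_summary(pairs)
        row = summary.set_index("chain").loc["beta"]
        distinct_tumor = {"CASA", "CASB", "CASC"}
        assert row.tumor_only + row.shared == len(distinct_tumor)
        shared_row = per_cdr3.set_index("cdr3_aa").loc["CASB"]
        assert shared_row.n_individuals == 1

    def test_mismatched_ids_error(self):
        with pytest.raises(ValueError):
            overlap_summary([(
                _rep("p1", "tumor", betas=("CASA",)),
                _rep("p2", "normal", betas=("CASA",)),
            )])


class TestSharingProfile:
    def test_counts(self):
        reps = [
            _rep("p1", "tumor", betas=("CASA", "CASB")),
            _rep("p2", "tumor", betas=("CASA",)),
            _rep("p3", "tumor", betas=("CASC",)),
        ]
        profile = sharing_profile(reps)
        assert profile.set_index("cdr3_aa").loc["CASA"].n_individuals == 2
        assert profile.total_reads.sum() == sum(r.df.read_count.sum() for r in reps)

    def test_specificity_labels(self):
        reps = [_rep("p1", "tumor", betas=("CASA",)),
                _rep("p2", "tumor", betas=("CASA",))]
        profile = sharing_profile(reps, known_specificities={"CASA": "EBV"})
        assert profile.iloc[0].specificity == "EBV"


class TestPairCooccurrence:
    def test_symmetric_identical_individuals(self):
        reps = [
            _rep("p1", "tumor", alphas=("CAVA",), betas=("CASB",)),
            _rep("p2", "tumor", alphas=("CAVA",), betas=("CASB",)),
        ]
        res = pair_cooccurrence_test(reps, n_iterations=50,
                                     rng=np.random.default_rng(0))
        assert res.n_observed_recurrent_pairs == 1
        assert res.p_value == 1.0

    def test_disjoint_individuals(self):
        reps = [
            _rep("p1", "tumor", alphas=("CAVA",), betas=("CASB",)),
            _rep("p2", "tumor", alphas=("CAVC",), betas=("CASD",)),
        ]
        res = pair_cooccurrence_test(reps, n_iterations=50,
                                     rng=np.random.default_rng(0))
        assert res.n_observed_recurrent_pairs == 0
        assert res.p_value == 1.0

    def test_statistic_invariant_to_clonotype_order(self):
        reps = []
        rng = np.random.default_rng(3)
        for i in range(4):
            alphas = ["".join(rng.choice(list(AA), 8)) for _ in range(5)]
            betas = ["".join(rng.choice(list(AA), 8)) for _ in range(5)]
            reps.append(_rep(f"p{i}", "tumor", alphas, betas))
        shuffled = [
            Repertoire(r.individual_id, r.tissue_label,
                       r.df.sample(frac=1, random_state=1).reset_index(drop=True))
            for r in reps
        ]
        a = pair_cooccurrence_test(reps, 20, np.random.default_rng(5))
        b = pair_cooccurrence_test(shuffled, 20, np.random.default_rng(5))
        assert a.n_observed_recurrent_pairs == b.n_observed_recurrent_pairs
        assert a.null_counts == b.null_counts

    def test_requires_two_eligible(self):
        with pytest.raises(ValueError):
            pair_cooccurrence_test(
                [_rep("p1", "tumor", alphas=("CAVA",), betas=("CASB",))],
                10, np.random.default_rng(0),
            )


def _null_cohort(rng, n_ind=8, pool=30, per=8):
    """Individuals drawing alpha/beta sets independently from shared pools:
    the permutation null holds exactly."""
    apool = ["".join(rng.choice(list(AA), 9)) for _ in range(pool)]
    bpool = ["".join(rng.choice(list(AA), 9)) for _ in range(pool)]
    reps = []
    for i in range(n_ind):
        alphas = rng.choice(apool, per, replace=False)
        betas = rng.choice(bpool, per, replace=False)
        reps.append(_rep(f"ind{i}", "tumor", list(alphas), list(betas)))
    return reps


def test_pair_test_p_value_calibration():
    """Under a null generator the p value is approximately uniform: over
    200 synthetic cohorts the fraction with p <= 0.1 is 0.10 +/- 0.06."""
    rng = np.random.default_rng(42)
    ps = []
    for _ in range(200):
        reps = _null_cohort(rng)
        res = pair_cooccurrence_test(reps, n_iterations=100, rng=rng)
        ps.append(res.p_value)
    frac = np.mean(np.asarray(ps) <= 0.1)
    assert abs(frac - 0.10) <= 0.06
    assert all(0 <= p <= 1 for p in ps)


class TestClustering:
    def test_identical_sequences_one_cluster(self):
        clusters = cluster_cdr3([("p1", "CASSLAPGATNEKLFF"), ("p2", "CASSLAPGATNEKLFF")])
        assert len(clusters) == 1
        assert clusters[0].individuals() == {"p1", "p2"}

    def test_single_substitution_below_threshold_splits(self):
        """15/16 = 93.75 % < 95 % -> two clusters."""
        a = "CASSLAPGATNEKLFF"
        b = "CASSLAPGATNEKLYF"
        assert sequence_identity(a, b) == pytest.approx(15 / 16)
        clusters = cluster_cdr3([("p1", a), ("p2", b)])
        assert len(clusters) == 2

    def test_partition_and_identity_audit(self):
        rng = np.random.default_rng(11)
        seqs = []
        for i in range(60):
            base = "C" + "".join(rng.choice(list(AA), int(rng.integers(8, 16)))) + "F"
            seqs.append((f"p{i % 7}", base))
            if rng.random() < 0.4:  # a near-duplicate with one substitution
                pos = int(rng.integers(1, len(base) - 1))
                variant = base[:pos] + "A" + base[pos + 1 :]
                seqs.append((f"p{(i + 1) % 7}", variant))
        clusters = cluster_cdr3(seqs, identity=0.95)
        members = [m for c in clusters for m in c.members]
        retained = [s for s in seqs if len(s[1]) >= 6]
        assert sorted(members) == sorted(retained)  # partition of the input
        for c in clusters:
            assert all(len(c.representative) >= len(seq) for _, seq in c.members)
            for _, seq in c.members:
                assert sequence_identity(c.representative, seq) >= 0.95

    def test_short_sequences_discarded(self):
        clusters = cluster_cdr3([("p1", "CASF"), ("p2", "CASSLGF")], min_length=6)
        assert len(clusters) == 1
        assert clusters[0].representative == "CASSLGF"

    def test_frame_output(self):
        clusters = cluster_cdr3([("p1", "CASSLGFFF"), ("p2", "CASSLGFFF")])
        frame = clusters_to_frame(clusters)
        assert len(frame) == 2
        assert set(frame.columns) == {
            "cluster", "representative", "individual_id", "cdr3_aa"
        }


class TestPMHCSharing:
    def _clusters(self):
        return cluster_cdr3(
            [("p1", "CASSLAPGATNEKLFF"), ("p2", "CASSLAPGATNEKLFF"),
             ("p3", "CAWSVGDEQFFGPGTR")]
        )

    def test_universal_pmhc_saturates(self):
        pmhc = {f"p{i}": {"HLA-A*02:01|SIINFEKL"} for i in range(1, 4)}
        res = pmhc_sharing_test(self._clusters(), pmhc, n_trials=10_000,
                                rng=np.random.default_rng(0))
        assert res.raw_fraction == 1.0
        assert res.adjusted_p == 1.0
        assert res.n_qualifying_clusters == 1
        assert res.n_two_individual_clusters == 1

    def test_no_shared_pmhc(self):
        pmhc = {"p1": {"A|x"}, "p2": {"B|y"}, "p3": {"C|z"}}
        res = pmhc_sharing_test(self._clusters(), pmhc, n_trials=10_000,
                                rng=np.random.default_rng(0))
        assert res.n_qualifying_clusters == 0
        assert res.raw_fraction == 0.0
        assert res.adjusted_p == 0.0

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            pmhc_sharing_test(self._clusters(), {}, n_trials=10,
                              rng=np.random.default_rng(0))


def test_repertoire_validation():
    with pytest.raises(ValueError):
        _rep("", "tumor", betas=("CASA",))
    with pytest.raises(ValueError):
        _rep("p1", "blood", betas=("CASA",))
    with pytest.raises(ValueError):
        _rep("p1", "tumor", betas=("CAS*A",))
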