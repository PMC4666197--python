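"""The CDR3 caller: cleaning, subsampling, extraction, filtering, collapse."""

import numpy as np
import pandas as pd
import pytest

from tcrseek import (
    ExtractionParams,
    centered_reads,
    clean_reads,
    collapse_to_aa,
    extract_cdr3,
    filter_clonotypes,
    simulate_repertoire,
    subsample_reads,
)
from tcrseek.extractor import ClonotypeTable
from tcrseek.reads import SequencingRead
from tcrseek.util import reverse_complement


def _read(seq, rid="r"):
    return SequencingRead(read_id=rid, sequence=seq)


class TestCleanReads:
    def test_length_strictly_greater_than_40(self):
        kept = clean_reads([_read("A" * 40), _read("C" * 41)])
        assert [r.sequence for r in kept] == ["C" * 41]

    def test_nonstandard_base_removed(self):
        assert clean_reads([_read("A" * 30 + "R" + "A" * 30)]) == []

    def test_all_n_read_passes_letter_filter(self):
        kept = clean_reads([_read("N" * 50)])
        assert len(kept) == 1


class TestSubsample:
    def test_full_sample_is_identity_set(self):
        reads = [_read("A" * 50, f"r{i}") for i in range(20)]
        out = subsample_reads(reads, 20, np.random.default_rng(0))
        assert {r.read_id for r in out} == {r.read_id for r in reads}

    def test_deterministic_and_seed_sensitive(self):
        reads = [_read("A" * 50, f"r{i}") for i in range(100)]
        a = subsample_reads(reads, 10, np.random.default_rng(1))
        b = subsample_reads(reads, 10, np.random.default_rng(1))
        c = subsample_reads(reads, 10, np.random.default_rng(2))
        assert [r.read_id for r in a] == [r.read_id for r in b]
        assert {r.read_id for r in a} != {r.read_id for r in c}

    def test_insufficient_depth_errors(self):
        with pytest.raises(ValueError, match="insufficient depth"):
            subsample_reads([_read("A" * 50)], 2, np.random.default_rng(0))

    def test_inclusion_probability(self):
        """Each read appears with empirical probability n/N (binomial 3-sigma)."""
        reads = [_read("A" * 50, f"r{i}") for i in range(100)]
        rng = np.random.default_rng(3)
        hits = np.zeros(100)
        reps = 1000
        for _ in range(reps):
            for r in subsample_reads(reads, 10, rng):
                hits[int(r.read_id[1:])] += 1
        p = 0.1
        sigma = np.sqrt(p * (1 - p) * reps)
        assert np.all(np.abs(hits - reps * p) < 3.5 * sigma)


def _flank_sufficient(t, ref, read_len, min_v, min_j):
    """Read-geometry oracle computed from the truth junction record."""
    v = ref.get(t.chain, "V", t.v_name)
    j = ref.get(t.chain, "J", t.j_name)
    s, e = t.cdr3_nt_interval
    c = e - s
    if c > read_len:
        return False
    f1 = (read_len - c) // 2
    f1 = min(f1, s)  # window may be clipped at the transcript start
    f2 = read_len - c - f1
    v_avail = f1 + (len(v.sequence) - v.anchor_offset) - t.junction.del_v3
    j_avail = f2 + (j.anchor_offset + 3) - t.junction.del_j5
    return v_avail >= min_v and j_avail >= min_j


@pytest.mark.parametrize("seed", [21, 22, 23, 24, 25])
def test_planted_read_oracle(ref, junction_model, seed):
    """Every flank-sufficient, error-free centered read yields exactly the
    truth CDR3 of its transcript (100 % recovery under the geometry)."""
    reps = simulate_repertoire(ref, "beta", 60, junction_model,
                               np.random.default_rng(seed))
    reads = centered_reads(reps, 101)
    params = ExtractionParams(12, 12, 0)
    table = extract_cdr3(reads, ref, params)
    called = table.cdr3_nt_set("beta")
    for t in reps:
        if _flank_sufficient(t, ref, 101, 12, 12):
            assert t.cdr3_nt in called


def test_short_reads_cannot_recover_long_cdr3(ref, beta_repertoire):
    """CDR3s longer than the read are never recovered at 50 nt."""
    long_cdr3 = [t for t in beta_repertoire if len(t.cdr3_nt) > 50]
    if not long_cdr3:
        pytest.skip("no CDR3 longer than 50 nt in this repertoire draw")
    reads = centered_reads(long_cdr3, 50)
    table = extract_cdr3(reads, ref, ExtractionParams(8, 8, 0))
    assert not (table.cdr3_nt_set() & {t.cdr3_nt for t in long_cdr3})


def test_exact_truth_recovery_on_101nt_reads(ref, beta_repertoire):
    """Centered 101-nt error-free reads at 12/12 return only truth CDR3s."""
    reads = centered_reads(beta_repertoire, 101)
    table = extract_cdr3(reads, ref, ExtractionParams(12, 12, 0))
    truth = {t.cdr3_nt for t in beta_repertoire}
    assert table.cdr3_nt_set("beta") <= truth
    # and read counts aggregate to at most one per input read
    assert table.total_reads <= len(reads)


def test_strand_symmetry(ref, beta_repertoire):
    reads = centered_reads(beta_repertoire[:150], 76)
    flipped = [
        SequencingRead(r.read_id, reverse_complement(r.sequence)) for r in reads
    ]
    params = ExtractionParams(12, 12, 0, both_strands=True)
    a = extract_cdr3(reads, ref, params).df
    b = extract_cdr3(flipped, ref, params).df
    cols = ["chain", "cdr3_nt", "v_name", "j_name", "read_count"]
    pd.testing.assert_frame_equal(
        a[cols].reset_index(drop=True), b[cols].reset_index(drop=True)
    )


def test_threshold_nesting(ref, beta_repertoire):
    """Raising either minimum alignment never adds a clonotype, and the
    one-pass grid semantics agree with direct per-cell extraction."""
    from tcrseek.reads import decoy_reads

    reads = centered_reads(beta_repertoire[:150], 50)
    reads += decoy_reads(ref, 300, 50, np.random.default_rng(31), mode="chimeric")
    tables = {}
    for v, j in [(8, 8), (14, 8), (8, 14), (14, 14), (20, 20), (26, 26)]:
        tables[(v, j)] = extract_cdr3(reads, ref, ExtractionParams(v, j, 0))

    def keyset(t):
        return set(map(tuple, t.df[["chain", "cdr3_nt", "v_name", "j_name"]].values))

    base = keyset(tables[(8, 8)])
    for (v, j), t in tables.items():
        assert keyset(t) <= base
    assert keyset(tables[(26, 26)]) <= keyset(tables[(20, 20)])
    assert keyset(tables[(14, 14)]) <= keyset(tables[(14, 8)]) & keyset(tables[(8, 14)])


def _toy_table():
    df = pd.DataFrame(
        [
            {"chain": "beta", "cdr3_nt": "TGTGCCAGCTTT", "cdr3_aa": "CASF",
             "v_name": "v1", "j_name": "j1", "read_count": 3, "has_stop": False},
            {"chain": "beta", "cdr3_nt": "TGCGCCAGCTTT", "cdr3_aa": "CASF",
             "v_name": "v1", "j_name": "j1", "read_count": 5, "has_stop": False},
            {"chain": "beta", "cdr3_nt": "TGTGCCTAATTT", "cdr3_aa": "CA*F",
             "v_name": "v1", "j_name": "j1", "read_count": 2, "has_stop": True},
            {"chain": "beta", "cdr3_nt": "TGTGCCAGCTT", "cdr3_aa": "",
             "v_name": "v2", "j_name": "j1", "read_count": 1, "has_stop": False},
        ]
    )
    return ClonotypeTable(df=df)


def test_filter_removes_stops_and_frameshifts():
    filtered = filter_clonotypes(_toy_table())
    assert len(filtered.df) == 2
    assert set(filtered.df.cdr3_aa) == {"CASF"}
    # an all-productive table passes unchanged
    again = filter_clonotypes(filtered)
    assert len(again.df) == 2


def test_collapse_to_aa_additivity():
    collapsed = collapse_to_aa(filter_clonotypes(_toy_table()))
    assert len(collapsed) == 1
    row = collapsed.iloc[0]
    assert row.read_count == 8
    assert row.n_nt_variants == 2


def test_collapse_single_clonotype():
    table = ClonotypeTable(df=_toy_table().df.iloc[[0]].reset_index(drop=True))
    collapsed = collapse_to_aa(table)
    assert collapsed.iloc[0].read_count == 3
    assert collapsed.iloc[0].n_nt_variants == 1
    assert collapsed.read_count.sum() == table.df.read_count.sum()
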