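"""Decision rules, admission semantics, and stream-level behavior."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bignorm.filtering import (
    CountVector,
    Decision,
    FilterParams,
    Reason,
    bignorm_decide,
    build_count_vector,
    decide_read,
    diginorm_decide,
    filter_stream,
)
from bignorm.io import ReadRecord
from bignorm.kmer import canonical, encode_kmer
from bignorm.sketch import CmsConfig, CountMinSketch, ExactCounter

from conftest import make_read, random_dna

K5 = FilterParams(k=5, q0=20, abundance=20, n_min=3)


def cv(counts, n_windows=None, n_valid=None, abundance=20):
    counts = np.asarray(counts)
    n = len(counts)
    return CountVector(
        counts=counts,
        n_windows=n_windows or n,
        n_valid=n_valid or n,
        n_high_quality=n,
        n_novel=int((counts < abundance).sum()),
    )


class TestBignormRule:
    def test_fresh_counter_accepts_first_read(self):
        read = make_read("ACGTACGTGGTCA", 40)
        c = ExactCounter()
        v = build_count_vector(read, c, K5)
        d = bignorm_decide(v, K5)
        assert d.accept and d.reason is Reason.NOVEL_ENOUGH
        assert v.n_novel == v.n_high_quality == v.n_windows

    def test_all_low_quality_rejected(self):
        read = make_read("ACGTACGTGGTCA", 10)  # every base below Q0=20
        d = decide_read(read, ExactCounter(), K5)
        assert not d.accept and d.reason is Reason.NO_ASSESSABLE_KMERS

    def test_n_min_boundary(self):
        v = cv([25, 25, 25, 0, 0])
        assert v.n_novel == 2
        assert not bignorm_decide(v, FilterParams(n_min=3)).accept
        assert bignorm_decide(v, FilterParams(n_min=2)).accept

    def test_count_vector_tallies_nested(self):
        # one N and one low-quality base give n_novel <= n_hq <= n_valid <= n_windows
        phreds = np.full(13, 40, dtype=np.int16)
        phreds[11] = 5
        read = ReadRecord("r", "ACGTNCGTGGTCA", phreds)
        v = build_count_vector(read, ExactCounter(), K5)
        assert v.n_novel <= v.n_high_quality <= v.n_valid <= v.n_windows
        assert len(v.counts) == v.n_high_quality
        assert v.n_valid < v.n_windows  # the N really masked windows


class TestDiginormRule:
    def test_fresh_counter_accepts(self):
        d = diginorm_decide("ACGTACGTGG", ExactCounter(), 5, 20)
        assert d.accept and d.reason is Reason.MEDIAN_BELOW and d.evidence == 0

    def test_median_threshold_strict(self):
        """Lower-median of [25,25,25,0,0] is 25 >= A=20: reject."""
        bases = "ACGTACGTG"  # 5 windows of k=5
        c = ExactCounter()
        wins = [bases[i : i + 5] for i in range(5)]
        for w in wins[:3]:
            for _ in range(25):
                c.add(canonical(encode_kmer(w), 5))
        d = diginorm_decide(bases, c, 5, 20)
        assert not d.accept and d.reason is Reason.MEDIAN_AT_OR_ABOVE
        assert d.evidence == 25

    def test_trace_thirty_identical_copies(self):
        """With A=20, exactly the first 20 copies of a read are accepted."""
        params = FilterParams(k=5, q0=0, abundance=20, mode="diginorm")
        c = ExactCounter()
        accepted = []
        read = make_read("ACGTACGTGGTCAAC", 40)
        from bignorm.filtering import admit

        for j in range(1, 31):
            d = decide_read(read, c, params)
            if d.accept:
                admit(read, c, params)
            accepted.append(d.accept)
        assert accepted == [True] * 20 + [False] * 10

    def test_quality_is_ignored(self):
        params = FilterParams(k=5, mode="diginorm")
        c = ExactCounter()
        hi = make_read("ACGTACGTGG", 40)
        lo = make_read("ACGTACGTGG", 2)
        assert decide_read(hi, c, params) == decide_read(lo, c, params)

    def test_short_read(self):
        params = FilterParams(k=20, mode="diginorm")
        d = decide_read(make_read("ACGT", 40), ExactCounter(), params)
        assert not d.accept and d.reason is Reason.TOO_SHORT


class TestAdmission:
    def test_second_copy_rejected_at_a1(self):
        from bignorm.filtering import admit

        params = FilterParams(k=5, q0=20, abundance=1, n_min=1)
        c = ExactCounter()
        read = make_read("ACGTACGTGGTCA", 40)
        d1 = decide_read(read, c, params)
        assert d1.accept
        admit(read, c, params)
        d2 = decide_read(read, c, params)
        assert not d2.accept and d2.reason is Reason.TOO_ABUNDANT

    def test_rejected_read_never_counts(self):
        params = FilterParams(k=5)
        sketch = CountMinSketch(CmsConfig(1, 2, seed=4))
        before = sketch.tables.copy()
        read = make_read("ACGTACGTGGTCA", 2)  # rejected: all low quality
        d = decide_read(read, sketch, params)
        assert not d.accept
        assert np.array_equal(sketch.tables, before)

    def test_n_windows_never_inserted(self):
        """Counter state with an N-read equals counting its N-free segments."""
        from bignorm.filtering import admit

        params = FilterParams(k=5, q0=0, n_min=1)
        read_n = make_read("ACGTANCGTGGTCA", 40)
        c1 = ExactCounter()
        admit(read_n, c1, params)
        # same content with the N split into separate segments
        c2 = ExactCounter()
        for seg in ("ACGTA", "CGTGGTCA"):
            admit(make_read(seg, 40), c2, params)
        assert c1._counts == c2._counts

    def test_diginorm_n_to_a_inflates_counts(self):
        """N→A coercion credits the A-substituted k-mer — the known defect."""
        from bignorm.filtering import admit

        params = FilterParams(k=5, mode="diginorm")
        c = ExactCounter()
        admit(make_read("CCGTNCCGTG", 40), c, params)
        # the window 'CCGTN' was counted as 'CCGTA'
        assert c.query(canonical(encode_kmer("CCGTA"), 5)) >= 1
        # bignorm-mode admission of the same read counts no such k-mer
        c2 = ExactCounter()
        admit(make_read("CCGTNCCGTG", 40), c2, FilterParams(k=5))
        assert c2.query(canonical(encode_kmer("CCGTA"), 5)) == 0

    def test_insert_hq_only_flag(self):
        from bignorm.filtering import admit

        phreds = np.full(13, 40, dtype=np.int16)
        phreds[0] = 2  # first window low quality
        read = ReadRecord("r", "ACGTACGTGGTCA", phreds)
        c_all, c_hq = ExactCounter(), ExactCounter()
        admit(read, c_all, FilterParams(k=5))
        admit(read, c_hq, FilterParams(k=5, insert_hq_only=True))
        assert c_all.n_inserts == c_hq.n_inserts + 1  # the low-quality window


class TestDecideDispatch:
    def test_q0_zero_is_vacuous(self):
        params = FilterParams(k=5, q0=0, n_min=1)
        c = ExactCounter()
        assert decide_read(make_read("ACGTACGTGG", 2), c, params).accept
        assert decide_read(make_read("ACGTACGTGG", 40), c, params).accept

    def test_too_short_both_modes(self):
        for mode in ("bignorm", "diginorm"):
            d = decide_read(
                make_read("ACG", 40), ExactCounter(), FilterParams(k=20, mode=mode)
            )
            assert not d.accept and d.reason is Reason.TOO_SHORT

    def test_decide_never_mutates(self):
        sketch = CountMinSketch(CmsConfig(1, 2, seed=4))
        before = sketch.tables.copy()
        for mode in ("bignorm", "diginorm"):
            decide_read(make_read("ACGTACGTGG", 40), sketch, FilterParams(k=5, mode=mode))
        assert np.array_equal(sketch.tables, before)


@given(
    counts=st.lists(st.integers(min_value=0, max_value=60), min_size=1, max_size=40),
    a=st.integers(min_value=1, max_value=50),
    a_bigger=st.integers(min_value=1, max_value=30),
    n_min=st.integers(min_value=1, max_value=10),
)
@settings(derandomize=True, max_examples=300)
def test_monotonicity_in_a_and_n_min(counts, a, a_bigger, n_min):
    """Frozen-counter decisions: accept at A implies accept at A' > A,
    and accept at n_min implies accept at any smaller n_min."""
    counts = np.asarray(counts)

    def decision(abund, nm):
        v = cv(counts, abundance=abund)
        return bignorm_decide(v, FilterParams(abundance=abund, n_min=nm)).accept

    if decision(a, n_min):
        assert decision(a + a_bigger, n_min)
        if n_min > 1:
            assert decision(a, n_min - 1)
    # diginorm monotonicity in A
    med = int(np.partition(counts, (len(counts) - 1) // 2)[(len(counts) - 1) // 2])
    if med < a:
        assert med < a + a_bigger


class TestStream:
    def test_empty_input(self):
        stats = filter_stream([], FilterParams(), ExactCounter())
        assert stats.reads_in == 0 and stats.percent_kept == 0.0
        assert stats.mean_phred_in is None

    def test_identical_reads_capped_at_a(self, rng):
        """n identical error-free reads: accepted count hits A and stays there."""
        bases = random_dna(rng, 60)
        reads = [make_read(bases, 40, f"r{i}") for i in range(50)]
        params = FilterParams(k=20, q0=20, abundance=20, n_min=3)
        stats = filter_stream(reads, params, ExactCounter())
        assert stats.reads_out == 20
        more = [make_read(bases, 40, f"s{i}") for i in range(80)]
        stats2 = filter_stream(more, params, ExactCounter())
        assert stats2.reads_out == 20  # independent of n for n >= A

    def test_quality_separation(self, rng):
        """Only phred-40 reads survive a mixed phred-2/40 stream at Q0=20."""
        reads = []
        for i in range(200):
            bases = random_dna(rng, 50)
            q = 40 if i % 2 == 0 else 2
            reads.append(make_read(bases, q, f"q{q}_{i}"))
        out = io.StringIO()
        stats = filter_stream(reads, FilterParams(k=20), ExactCounter(), output=out)
        accepted_ids = [l[1:] for l in out.getvalue().splitlines()[::4]]
        assert accepted_ids and all(rid.startswith("q40") for rid in accepted_ids)
        assert stats.reasons["NO_ASSESSABLE_KMERS"] == 100

    def test_stats_and_log_consistency(self, rng):
        reads = [make_read(random_dna(rng, 40), 30, f"r{i}") for i in range(30)]
        out, log = io.StringIO(), io.StringIO()
        stats = filter_stream(
            reads, FilterParams(k=10), ExactCounter(), output=out, decision_log=log
        )
        emitted = out.getvalue().splitlines()
        assert len(emitted) == 4 * stats.reads_out
        log_lines = log.getvalue().splitlines()
        assert log_lines[0].startswith("read_id\t")
        assert len(log_lines) == 1 + stats.reads_in
        assert sum(stats.reasons.values()) == stats.reads_in

    def test_small_sketch_never_beats_exact_in_diginorm(self, rng):
        """CMS overestimates only push medians up: kept(CMS) <= kept(exact)."""
        genome = random_dna(rng, 2000)
        reads = []
        for i in range(800):
            s = rng.integers(0, len(genome) - 50)
            reads.append(make_read(genome[s : s + 50], 40, f"r{i}"))
        params = FilterParams(k=10, abundance=5, mode="diginorm")
        kept_cms = filter_stream(reads, params, CountMinSketch(CmsConfig(1, 1, seed=0)))
        kept_exact = filter_stream(reads, params, ExactCounter())
        assert kept_cms.reads_out <= kept_exact.reads_out

    def test_paired_independent_vs_rescue(self, rng):
        bases = random_dna(rng, 50)
        # mate 1 high quality, mate 2 hopeless quality
        pairs = [
            (make_read(bases, 40, f"a{i}/1"), make_read(bases, 2, f"a{i}/2"))
            for i in range(5)
        ]
        out = io.StringIO()
        stats = filter_stream(
            pairs, FilterParams(k=20), ExactCounter(), output=out, paired=True
        )
        ids = [l[1:] for l in out.getvalue().splitlines()[::4]]
        assert all(i.endswith("/1") for i in ids)  # mates judged alone

        out2 = io.StringIO()
        params = FilterParams(k=20, paired_policy="either-mate-rescues")
        stats2 = filter_stream(pairs, params, ExactCounter(), output=out2, paired=True)
        ids2 = [l[1:] for l in out2.getvalue().splitlines()[::4]]
        assert len(ids2) == 2 * len(ids)  # pairs emitted in full
        assert stats2.reasons.get("MATE_RESCUED", 0) > 0

    def test_stream_determinism(self, rng):
        reads = [make_read(random_dna(rng, 60), 35, f"r{i}") for i in range(100)]
        outs = []
        for _ in range(2):
            out = io.StringIO()
            filter_stream(
                reads, FilterParams(k=15), CountMinSketch(CmsConfig(1, 2, seed=11)),
                output=out,
            )
            outs.append(out.getvalue())
        assert outs[0] == outs[1] and outs[0]


def test_invalid_params():
    with pytest.raises(ValueError):
        FilterParams(k=0)
    with pytest.raises(ValueError):
        FilterParams(mode="median")
    with pytest.raises(ValueError):
        FilterParams(n_min=0)
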