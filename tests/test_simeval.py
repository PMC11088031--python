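import numpy as np
import pytest

from plrex.pair_finalize import CONNECTED, UNCONNECTED, PseudoLongRead
from plrex.seqcore import decode_codes, encode_codes, revcomp_codes
from plrex.simeval import (RepeatSpec, ambiguous_mate_positions,
                           evaluate_run, gap_edit_distance,
                           modified_gap_edit_distance, simulate_genome,
                           simulate_pairs, true_gap_codes)
from plrex.task_engine import LengthWindow


def _levenshtein_oracle(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestSimulateGenome:
    def test_reproducible_per_seed(self):
        a = simulate_genome(100, 5)
        b = simulate_genome(100, 5)
        c = simulate_genome(100, 6)
        assert a == b
        assert a != c

    def test_repeat_injection_duplicates_sequence(self):
        g = simulate_genome(5000, 9, RepeatSpec(count=1, length=500,
                                                divergence=0.0))
        s = str(g)
        seen = set()
        dup = False
        for i in range(len(s) - 99):
            sub = s[i:i + 100]
            if sub in seen:
                dup = True
                break
            seen.add(sub)
        assert dup, "an exact repeat must duplicate some 100-mer"

    def test_repeat_copy_divergence(self):
        # same seed: the only difference between divergence 0 and 2% is the
        # per-base mutation of the pasted copy (~2% of 500 positions)
        exact = simulate_genome(5000, 9, RepeatSpec(1, 500, 0.0))
        diverged = simulate_genome(5000, 9, RepeatSpec(1, 500, 0.02))
        diff = np.flatnonzero(exact.codes != diverged.codes)
        assert 1 <= diff.shape[0] <= 40

    def test_base_composition_near_uniform(self):
        g = simulate_genome(100_000, 3)
        freqs = np.bincount(g.codes, minlength=4) / 100_000
        assert np.all(np.abs(freqs - 0.25) < 0.01)


class TestSimulatePairs:
    def test_pair_count_formula(self):
        g = simulate_genome(100_000, 1)
        sim = simulate_pairs(g, 30.0, 100, 500, 10, (460, 540), 0.0, 2)
        assert sim.n_pairs == 15_000

    def test_noiseless_reads_are_genome_substrings(self):
        g = simulate_genome(4000, 4)
        sim = simulate_pairs(g, 10.0, 50, 300, 20, (210, 390), 0.0, 5)
        gs = str(g)
        grc = decode_codes(revcomp_codes(g.codes))
        for i in range(2 * sim.n_pairs):
            read = decode_codes(sim.store.get_codes(i))
            assert read in gs or read in grc

    def test_reads_match_recorded_fragments(self):
        g = simulate_genome(4000, 4)
        sim = simulate_pairs(g, 5.0, 50, 300, 20, (210, 390), 0.0, 5)
        for p in range(sim.n_pairs):
            t = sim.truth.iloc[p]
            s, e = int(t["start"]), int(t["end"])
            frag = g.codes[s:e] if t["strand"] > 0 else revcomp_codes(g.codes[s:e])
            assert np.array_equal(sim.read1_codes(p), frag[:50])
            assert np.array_equal(sim.read2_codes(p),
                                  revcomp_codes(frag[-50:]))
            gap = true_gap_codes(g, s, e, int(t["strand"]), 50)
            assert np.array_equal(gap, frag[50:-50])
            assert gap.shape[0] == t["insert"] - 100

    def test_insert_mean_within_three_standard_errors(self):
        g = simulate_genome(200_000, 8)
        sim = simulate_pairs(g, 10.0, 100, 500, 10, (460, 540), 0.0, 9)
        inserts = sim.truth["insert"].to_numpy()
        se = 10 / np.sqrt(len(inserts))
        assert abs(inserts.mean() - 500) < 3 * se

    def test_error_rate_matches_request(self):
        g = simulate_genome(50_000, 8)
        sim = simulate_pairs(g, 10.0, 100, 500, 10, (460, 540), 0.01, 9)
        n_err = (sim.truth["n_err_read1"] + sim.truth["n_err_read2"]).sum()
        total = 2 * 100 * sim.n_pairs
        assert 0.007 < n_err / total < 0.013

    def test_overlapping_insert_bounds_rejected(self):
        g = simulate_genome(10_000, 1)
        with pytest.raises(ValueError):
            simulate_pairs(g, 5.0, 100, 210, 10, (150, 260), 0.0, 2)


class TestGapEditDistance:
    def test_trivial_cases(self):
        assert gap_edit_distance("ACGT", "ACGT") == 0
        assert gap_edit_distance("ACGT", "ACTT") == 1
        assert gap_edit_distance("", "ACG") == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dp_oracle_on_random_instances(self, seed):
        rng = np.random.Generator(np.random.PCG64(seed))
        for _ in range(50):
            n = int(rng.integers(1, 60))
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            b = list(a)
            for _ in range(int(rng.integers(0, 6))):
                op = rng.integers(0, 3)
                pos = int(rng.integers(0, max(1, len(b))))
                if op == 0 and b:
                    b[pos] = "ACGT"[int(rng.integers(0, 4))]
                elif op == 1 and b:
                    del b[pos]
                else:
                    b.insert(pos, "ACGT"[int(rng.integers(0, 4))])
            b = "".join(b)
            if not b:
                continue
            assert gap_edit_distance(a, b) == _levenshtein_oracle(a, b)


class TestModifiedEditDistance:
    def test_formula(self):
        assert modified_gap_edit_distance(5, 300, 297) == 2
        assert modified_gap_edit_distance(4, 300, 300) == 4

    def test_pure_deletion_has_zero_modified_distance(self):
        rng = np.random.Generator(np.random.PCG64(2))
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        b = a[:10] + a[12:]  # two bases deleted
        ed = gap_edit_distance(b, a)
        assert ed == _levenshtein_oracle(b, a) == 2
        assert modified_gap_edit_distance(ed, len(a), len(b)) == 0

    def test_never_exceeds_edit_distance(self):
        rng = np.random.Generator(np.random.PCG64(3))
        for _ in range(30):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(10, 50))))
            ed = gap_edit_distance(a, b)
            med = modified_gap_edit_distance(ed, len(b), len(a))
            assert 0 <= med <= ed
            if len(a) == len(b):
                assert med == ed


class TestAmbiguousMatePositions:
    def _sim_one(self, genome, start, insert, read_len=100):
        frag = genome.codes[start:start + insert]
        return frag[:read_len], revcomp_codes(frag[-read_len:])

    def test_unique_placement_on_random_genome(self):
        g = simulate_genome(10_000, 13)
        w = LengthWindow(460, 540)
        for start in (1000, 3000, 5000):
            r1, r2 = self._sim_one(g, start, 500)
            n = ambiguous_mate_positions(g, r1, r2, start, start + 500, 1, w)
            assert n == 1

    def test_tandem_repeat_creates_multiple_placements(self):
        rng = np.random.Generator(np.random.PCG64(17))
        unit = rng.integers(0, 4, 500, dtype=np.uint8)
        from plrex.seqcore import EncodedSequence
        codes = np.concatenate([rng.integers(0, 4, 2000, dtype=np.uint8),
                                unit, unit,
                                rng.integers(0, 4, 2000, dtype=np.uint8)])
        g = EncodedSequence(codes)
        # mate lies in the first repeat copy; the second copy offers an
        # alternative placement 500 bases downstream, inside the window
        start = 2000 - 300
        insert = 700  # read 2 occupies [2400, 2500): fully in copy 1
        r1, r2 = self._sim_one(g, start, insert)
        w = LengthWindow(300, 1400)
        n = ambiguous_mate_positions(g, r1, r2, start, start + insert, 1, w)
        assert n >= 2

    def test_max_hamming_zero_is_exact_occurrence_count(self):
        g = simulate_genome(8000, 19)
        w = LengthWindow(460, 540)
        r1, r2 = self._sim_one(g, 4000, 500)
        n = ambiguous_mate_positions(g, r1, r2, 4000, 4500, 1, w,
                                     max_hamming=0)
        assert n == 1


@pytest.fixture(scope="module")
def tiny_sim():
    g = simulate_genome(30_000, 23)
    return simulate_pairs(g, 2.0, 100, 500, 10, (460, 540), 0.0, 24)


class TestEvaluateRun:
    def _fake_run(self, sim, read_len=100, break_pair=None):
        results = []
        for p in range(sim.n_pairs):
            t = sim.truth.iloc[p]
            frag = true_gap_codes(sim.genome, int(t["start"]), int(t["end"]),
                                  int(t["strand"]), read_len)
            codes = np.concatenate([sim.read1_codes(p), frag,
                                    revcomp_codes(sim.read2_codes(p))])
            if break_pair is not None and p == break_pair:
                codes = codes.copy()
                codes[read_len + 5] = (codes[read_len + 5] + 1) % 4
                codes[read_len + 9] = (codes[read_len + 9] + 1) % 4
                codes[read_len + 15] = (codes[read_len + 15] + 1) % 4
            results.append(PseudoLongRead(
                pair_id=p, status=CONNECTED, codes=codes, gap_start=read_len,
                gap_end=codes.shape[0] - read_len))
        return results

    def test_exact_gaps_give_zero_error_rate(self, tiny_sim):
        w = LengthWindow(460, 540)
        ev = evaluate_run(self._fake_run(tiny_sim), tiny_sim, w)
        assert ev.error_rate == 0.0
        assert ev.n_error_free == ev.n_connected == tiny_sim.n_pairs

    def test_error_rate_is_edits_over_produced_gap_lengths(self, tiny_sim):
        w = LengthWindow(460, 540)
        ev = evaluate_run(self._fake_run(tiny_sim, break_pair=0), tiny_sim, w)
        total_len = int(ev.per_pair["gap_len_produced"].sum())
        assert ev.per_pair["edit_distance"].sum() == 3
        assert ev.error_rate == pytest.approx(3 / total_len)
        assert ev.n_error_free == ev.n_connected - 1

    def test_stratified_rates_recompose_to_aggregate(self, tiny_sim):
        w = LengthWindow(460, 540)
        ev = evaluate_run(self._fake_run(tiny_sim, break_pair=1), tiny_sim, w)
        edits = lens = 0
        for cat in ("A", "B"):
            d = ev.by_category.get(cat)
            if d is None or d["n_connected"] == 0:
                continue
            sub = ev.per_pair[np.where(
                ev.per_pair["n_mate_positions"] > 1, "A", "B") == cat]
            assert d["n_connected"] == len(sub)
            edits += int(sub["edit_distance"].sum())
            lens += int(sub["gap_len_produced"].sum())
        assert edits / lens == pytest.approx(ev.error_rate)

    def test_unconnected_pairs_are_ignored(self, tiny_sim):
        w = LengthWindow(460, 540)
        results = self._fake_run(tiny_sim)
        results[0] = PseudoLongRead(pair_id=0, status=UNCONNECTED)
        ev = evaluate_run(results, tiny_sim, w)
        assert ev.n_connected == tiny_sim.n_pairs - 1

    def test_unknown_pair_id_raises(self, tiny_sim):
        w = LengthWindow(460, 540)
        bad = [PseudoLongRead(pair_id=10**6, status=CONNECTED,
                              codes=encode_codes("ACGT" * 50), gap_start=10,
                              gap_end=100)]
        with pytest.raises(KeyError):
            evaluate_run(bad, tiny_sim, w)
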