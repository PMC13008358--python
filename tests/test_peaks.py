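"""Poisson window test, BH adjustment, peak merging and replicate consensus."""

import itertools
import math

import numpy as np
import pytest

from ac4c.models import Peak, TranscriptModel
from ac4c.peaks import (
    CallerParams,
    bh_adjust,
    call_peaks,
    consensus_peaks,
    window_enrichment,
)
from tests.conftest import make_track

# textbook-form parameters: window-local lambda, library-size scaling
LITERAL = dict(background="window", normalization="library")


def poisson_tail(k: int, lam: float) -> float:
    """Brute-force upper tail P(X >= k) by direct summation (oracle).

    Sums e^-lam lam^j / j! upward from j = k (log-space terms) until the
    additions fall below machine precision, avoiding the cancellation a
    1 - CDF complement would suffer in deep tails.
    """
    if k <= 0:
        return 1.0
    log_term = -lam + k * math.log(lam) - math.lgamma(k + 1)
    total = 0.0
    j = k
    while True:
        term = math.exp(log_term)
        total += term
        if term < total * 1e-17 or term == 0.0:
            break
        j += 1
        log_term += math.log(lam) - math.log(j)
    return min(1.0, total)


def bh_stepup(pvalues):
    """Hand step-up BH (oracle): q_(i) = min over j>=i of p_(j) m / j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q


class TestWindowEnrichment:
    def test_zero_acrip_gives_p_one_fe_zero(self):
        a = make_track({"tx1": [0, 0, 0]}, role="acrip", library_size=100)
        i = make_track({"tx1": [5, 5, 5]}, role="input", library_size=100)
        tab = window_enrichment(a, i, CallerParams(**LITERAL))
        assert (tab["pvalue"] == 1.0).all()
        assert (tab["fe"] == 0.0).all()

    def test_poisson_example_lambda_five(self):
        # equal library sizes, input 4 everywhere, pseudocount 1 -> lam = 5;
        # acrip 20 in one window: P(Poisson(5) >= 20) ~ 1.15e-7 by summation
        a = make_track({"tx1": [20, 4, 4, 4]}, role="acrip", library_size=1000)
        i = make_track({"tx1": [4, 4, 4, 4]}, role="input", library_size=1000)
        tab = window_enrichment(a, i, CallerParams(**LITERAL))
        expect = poisson_tail(20, 5.0)
        assert tab["pvalue"][0] == pytest.approx(expect, rel=1e-9)
        assert tab["fe"][0] == pytest.approx(4.0)

    def test_library_scaling_halves_fe(self):
        # acrip library twice the input library, equal raw counts, zero
        # pseudocount -> fe = 0.5 in every window
        a = make_track({"tx1": [8, 8]}, role="acrip", library_size=2000)
        i = make_track({"tx1": [8, 8]}, role="input", library_size=1000)
        params = CallerParams(input_pseudocount=0.0, **LITERAL)
        tab = window_enrichment(a, i, params)
        assert np.allclose(tab["fe"], 0.5)

    def test_mismatched_grids_rejected(self):
        a = make_track({"tx1": [1, 2, 3]}, role="acrip")
        i = make_track({"tx1": [1, 2]}, role="input")
        with pytest.raises(ValueError, match="mismatch"):
            window_enrichment(a, i, CallerParams())

    @pytest.mark.parametrize("lam,kmax", [(0.5, 30), (5.0, 80), (40.0, 200)])
    def test_tail_matches_brute_force(self, lam, kmax):
        from scipy.stats import poisson

        for k in range(0, kmax + 1, 7):
            expect = poisson_tail(k, lam)
            got = float(poisson.sf(k - 1, lam))
            assert got == pytest.approx(expect, rel=1e-9, abs=1e-300)


class TestBHAdjust:
    def test_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.04])
        assert np.allclose(q, [0.03, 0.03, 0.04])

    def test_all_equal_stay_equal(self):
        q = bh_adjust([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_stepup_oracle_on_permutations(self):
        base = [0.001, 0.02, 0.15, 0.5, 0.99]
        for perm in itertools.permutations(base, 4):
            assert np.allclose(bh_adjust(list(perm)), bh_stepup(list(perm)))

    def test_order_preservation(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        # sorting by p must sort q (monotone step-up; ties in q allowed)
        assert (np.diff(q[np.argsort(p)]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([])


def _paired_tracks(acrip_counts, input_counts, lib=10_000):
    a = make_track(acrip_counts, role="acrip", library_size=lib)
    i = make_track(input_counts, role="input", library_size=lib)
    return a, i


class TestCallPeaks:
    def test_flat_tracks_give_no_peaks(self):
        a, i = _paired_tracks({"tx1": [5] * 20}, {"tx1": [5] * 20})
        assert call_peaks(a, i, CallerParams(**LITERAL)) == []

    def test_adjacent_significant_windows_merge(self):
        base = [4] * 20
        sig = list(base)
        sig[8] = sig[9] = sig[10] = 60
        a, i = _paired_tracks({"tx1": sig}, {"tx1": base})
        peaks = call_peaks(a, i, CallerParams(**LITERAL))
        assert len(peaks) == 1
        (p,) = peaks
        assert (p.start, p.end) == (400, 550)
        assert p.summit == 400  # leftmost maximal window on ties
        assert p.fe > 2 and p.qvalue < 0.05

    def test_distant_runs_stay_separate(self):
        base = [4] * 30
        sig = list(base)
        for w in (3, 4):
            sig[w] = 60
        for w in (20, 21):
            sig[w] = 80
        a, i = _paired_tracks({"tx1": sig}, {"tx1": base})
        peaks = call_peaks(a, i, CallerParams(**LITERAL))
        assert len(peaks) == 2

    def test_min_windows_drops_singletons(self):
        base = [4] * 30
        sig = list(base)
        sig[5] = 100
        a, i = _paired_tracks({"tx1": sig}, {"tx1": base})
        assert call_peaks(a, i, CallerParams(**LITERAL)) == []
        relaxed = CallerParams(min_windows=1, **LITERAL)
        assert len(call_peaks(a, i, relaxed)) == 1

    def test_all_returned_peaks_pass_screen(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(10, size=60)
        sig = base.copy()
        sig[10:14] *= 6
        sig[40:43] *= 3
        a, i = _paired_tracks({"tx1": sig.tolist()}, {"tx1": base.tolist()})
        params = CallerParams(**LITERAL)
        for p in call_peaks(a, i, params):
            assert p.fe > params.min_fe
            assert p.qvalue < params.max_q
            assert p.start <= p.summit < p.end

    def test_end_trimmed_to_transcript(self):
        models = {"tx1": TranscriptModel("tx1", "g1", 0, 130, 0)}
        base = [10, 10, 10]
        sig = [90, 90, 90]
        a, i = _paired_tracks({"tx1": sig}, {"tx1": base})
        peaks = call_peaks(a, i, CallerParams(**LITERAL), models)
        assert peaks and peaks[0].end == 130


class TestConsensus:
    def _peak(self, tid, start, end, fe=4.0):
        return Peak(tid, start, end, start, 40, 10, fe, 1e-6, 1e-5)

    def test_identical_peak_in_three_replicates(self):
        reps = [[self._peak("tx1", 100, 300)] for _ in range(3)]
        cons = consensus_peaks(reps)
        assert len(cons) == 1
        assert cons[0].support == 3
        assert (cons[0].start, cons[0].end) == (100, 300)

    def test_single_replicate_peak_dropped(self):
        reps = [[self._peak("tx1", 100, 300)], [], []]
        assert consensus_peaks(reps, min_support=2) == []

    def test_hand_traced_single_linkage(self):
        reps = [
            [self._peak("tx1", 100, 300, 4.0), self._peak("tx1", 800, 900, 6.0)],
            [self._peak("tx1", 250, 450, 5.0)],
            [],
        ]
        cons = consensus_peaks(reps, min_support=2)
        assert len(cons) == 1
        (c,) = cons
        assert (c.start, c.end, c.support) == (100, 450, 2)
        assert c.mean_fe == pytest.approx(4.5)

    def test_order_invariance(self):
        reps = [
            [self._peak("tx1", 0, 120), self._peak("tx2", 10, 90)],
            [self._peak("tx1", 100, 260)],
            [self._peak("tx2", 50, 200)],
        ]
        a = consensus_peaks(reps)
        b = consensus_peaks(list(reversed(reps)))
        assert a == b

    def test_min_support_exceeding_replicates_rejected(self):
        with pytest.raises(ValueError):
            consensus_peaks([[], []], min_support=3)


class TestNullCalibration:
    def test_type_one_error_at_most_nominal(self):
        """Window p-values on Poisson null data reject at <= alpha + 3 SE."""
        from ac4c.simulate import SimConfig, simulate_experiment

        tot = rej = 0
        for seed in range(20):
            cfg = SimConfig(
                n_transcripts=20, n_replicates=1, dispersion=None,
                baseline_enrichment=1.0, misa_effect=1.0, seed=seed,
            )
            tracks, _ = simulate_experiment(cfg, [("control", "day6", 1)])
            acrip = next(t for t in tracks if t.role.value == "acrip")
            inp = next(t for t in tracks if t.role.value == "input")
            tab = window_enrichment(acrip, inp, CallerParams())
            tot += len(tab)
            rej += int((tab["pvalue"] < 0.05).sum())
        assert rej / tot <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / tot)
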