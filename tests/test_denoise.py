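"""Chimera flagging, error calibration and the frequency threshold filter."""

import numpy as np
import pytest

from flukeprint.denoise import (
    ErrorCalibration,
    apply_threshold,
    calibrate_error,
    ceil_percent,
    detect_chimeras,
)
from flukeprint.errors import CalibrationError
from flukeprint.readproc import UniqueSequence as U
from flukeprint._seq import hamming


def oracle_detect_chimeras(uniques, skew=2.0, min_diffs=2):
    """Brute force over parent pairs and breakpoints, sequential processing."""
    flags = [False] * len(uniques)
    accepted = []
    for i, u in enumerate(uniques):
        L = len(u.seq)
        parents = [
            j for j in accepted
            if uniques[j].count >= skew * u.count and len(uniques[j].seq) == L
        ]
        found = False
        for a in parents:
            for b in parents:
                A, B = uniques[a].seq, uniques[b].seq
                if hamming(u.seq, A) < min_diffs or hamming(u.seq, B) < min_diffs:
                    continue
                for k in range(L + 1):
                    if A[:k] + B[k:] == u.seq:
                        found = True
                        break
                if found:
                    break
            if found:
                break
        flags[i] = found
        if not found:
            accepted.append(i)
    return flags


def _mutate(rng, seq, n):
    pos = rng.choice(len(seq), n, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestChimeraDetection:
    def test_constructed_crossover_flagged(self, rng):
        A = "".join(rng.choice(list("ACGT"), 450))
        B = _mutate(rng, A, 12)
        chim = A[:200] + B[200:]
        flags = detect_chimeras([U(A, 30, 0.5), U(B, 22, 0.37), U(chim, 10, 0.13)])
        assert flags == [False, False, True]

    def test_skew_boundary_not_flagged(self, rng):
        A = "".join(rng.choice(list("ACGT"), 450))
        B = _mutate(rng, A, 12)
        chim = A[:200] + B[200:]
        # parents only 20 reads vs candidate 15: skew < 2
        flags = detect_chimeras([U(A, 20, 0.4), U(B, 20, 0.35), U(chim, 15, 0.25)])
        assert flags == [False, False, False]

    def test_single_haplotype_errors_never_flagged(self, rng):
        A = "".join(rng.choice(list("ACGT"), 450))
        uniques = [U(A, 1000, 0.9)]
        for i in range(20):
            uniques.append(U(_mutate(rng, A, 1 + i % 3), 2, 0.002))
        flags = detect_chimeras(uniques)
        assert not any(flags)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            detect_chimeras([U("AAAA", 1, 0.1), U("CCCC", 9, 0.9)])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_oracle_on_random_mixtures(self, seed):
        rng = np.random.default_rng(seed)
        A = "".join(rng.choice(list("ACGT"), 80))
        B = _mutate(rng, A, 10)
        C = _mutate(rng, A, 14)
        pool = [U(A, 200, 0.0), U(B, 150, 0.0), U(C, 100, 0.0)]
        # random crossovers and error variants at assorted counts
        for i in range(12):
            parents = [A, B, C]
            pa, pb = rng.choice(3, 2, replace=False)
            k = int(rng.integers(5, 75))
            seq = parents[pa][:k] + parents[pb][k:]
            pool.append(U(seq, int(rng.integers(1, 60)), 0.0))
        for i in range(8):
            pool.append(U(_mutate(rng, A, int(rng.integers(1, 4))),
                          int(rng.integers(1, 30)), 0.0))
        pool = [u for u in pool]
        # deduplicate (crossovers may reproduce a parent exactly)
        seen, uniq = set(), []
        for u in pool:
            if u.seq not in seen:
                seen.add(u.seq)
                uniq.append(u)
        uniq.sort(key=lambda u: (-u.count, u.seq))
        total = sum(u.count for u in uniq)
        uniq = [U(u.seq, u.count, u.count / total) for u in uniq]
        assert detect_chimeras(uniq) == oracle_detect_chimeras(uniq)

    def test_flags_90_percent_of_strong_crossovers_and_no_parents(self, rng):
        A = "".join(rng.choice(list("ACGT"), 450))
        B = _mutate(rng, A, 20)
        uniques = [U(A, 5000, 0.45), U(B, 4000, 0.36)]
        chims = []
        for i in range(30):
            k = int(rng.integers(50, 400))
            seq = A[:k] + B[k:] if i % 2 else B[:k] + A[k:]
            if seq not in (A, B):
                chims.append(seq)
        chims = sorted(set(chims))
        for s in chims:
            uniques.append(U(s, 10, 0.001))  # parents >= 400x candidate
        uniques.sort(key=lambda u: -u.count)
        flags = detect_chimeras(uniques)
        assert flags[0] is False and flags[1] is False
        flagged = sum(flags[2:])
        assert flagged >= 0.9 * len(chims)


class TestCalibration:
    def test_rate_is_top_error_over_denominator(self):
        controls = {"POS1": [U("A" * 400, 9700, 0.97), U("C" * 400, 200, 0.02),
                             U("G" * 400, 100, 0.01)]}
        cal = calibrate_error(controls, {"POS1": "A" * 400},
                              denominators={"POS1": 10_000})
        assert cal.per_control_rate["POS1"] == pytest.approx(0.02)

    def test_pure_control_has_zero_rate(self):
        cal = calibrate_error({"POS1": [U("A" * 400, 500, 1.0)]},
                              {"POS1": "A" * 400})
        assert cal.per_control_rate["POS1"] == 0.0
        assert cal.threshold == 0.0

    def test_ceil_percent_rounding_reproduces_two_percent(self):
        assert ceil_percent(0.017) == pytest.approx(0.02)
        assert ceil_percent(0.02) == pytest.approx(0.02)
        assert ceil_percent(0.0201) == pytest.approx(0.03)
        controls = {
            "POS1": [U("A" * 400, 983, 0.983), U("C" * 400, 17, 0.017)],
        }
        cal = calibrate_error(controls, {"POS1": "A" * 400},
                              denominators={"POS1": 1000})
        assert cal.max_rate == pytest.approx(0.017)
        assert cal.threshold == pytest.approx(0.02)

    def test_raw_max_rounding(self):
        controls = {"POS1": [U("A" * 400, 983, 0.983), U("C" * 400, 17, 0.017)]}
        cal = calibrate_error(controls, {"POS1": "A" * 400},
                              denominators={"POS1": 1000}, rounding="raw-max")
        assert cal.threshold == pytest.approx(0.017)

    def test_summary_statistics_across_controls(self):
        controls = {
            "P1": [U("A" * 400, 990, 0.99), U("C" * 400, 10, 0.01)],
            "P2": [U("A" * 400, 980, 0.98), U("C" * 400, 20, 0.02)],
        }
        cal = calibrate_error(controls, {"P1": "A" * 400, "P2": "A" * 400})
        assert cal.max_rate == pytest.approx(0.02)
        assert cal.mean_rate == pytest.approx(0.015)
        assert cal.sd_rate == pytest.approx(np.std([0.01, 0.02], ddof=1))
        assert cal.threshold >= cal.max_rate

    def test_empty_control_excluded_with_warning(self):
        controls = {"P1": [U("A" * 400, 100, 1.0)], "P2": []}
        with pytest.warns(UserWarning):
            cal = calibrate_error(controls, {"P1": "A" * 400, "P2": "A" * 400})
        assert cal.excluded_controls == ["P2"]

    def test_all_controls_empty_is_an_error(self):
        with pytest.warns(UserWarning), pytest.raises(CalibrationError):
            calibrate_error({"P1": []}, {"P1": "A" * 400})

    def test_replicate_controls_calibrate_stably(self, rng):
        """Over 20 replicate simulated controls the mean rate is stable
        (CV < 50%) and each rate is bounded by the total error fraction."""
        true = "".join(rng.choice(list("ACGT"), 400))
        rates = []
        for rep in range(20):
            n = 5000
            n_err = rng.binomial(n, 0.05)
            counter = {}
            for _ in range(n_err):
                s = _mutate(rng, true, int(rng.integers(1, 3)))
                counter[s] = counter.get(s, 0) + 1
            uniques = [U(true, n - n_err, (n - n_err) / n)]
            uniques += [U(s, c, c / n) for s, c in counter.items()]
            uniques.sort(key=lambda u: (-u.count, u.seq))
            cal = calibrate_error({"P": uniques}, {"P": true},
                                  denominators={"P": n})
            assert cal.per_control_rate["P"] <= n_err / n
            rates.append(cal.per_control_rate["P"])
        rates = np.array(rates)
        assert rates.std() / rates.mean() < 0.5


class TestThreshold:
    def test_boundary_is_inclusive(self):
        uniques = [U("A" * 400, 850, 0.85), U("C" * 400, 21, 0.021),
                   U("G" * 400, 15, 0.015)]
        kept = apply_threshold(uniques, 0.02)
        assert [u.frequency for u in kept] == [0.85, 0.021]

    def test_low_depth_sample_sequence_removed(self):
        # 510 de-replicated reads out of 221,922 merged contigs
        u = U("A" * 400, 510, 510 / 221_922)
        assert apply_threshold([u], 0.02) == []

    def test_zero_threshold_is_identity_minus_chimeras(self):
        uniques = [U("A" * 400, 10, 0.8), U("C" * 400, 2, 0.2)]
        assert apply_threshold(uniques, 0.0) == uniques
        assert apply_threshold(uniques, 0.0, [False, True]) == uniques[:1]

    def test_idempotent_and_monotone(self, rng):
        uniques = [
            U(f"{i}" * 10, c, f)
            for i, (c, f) in enumerate(
                zip(rng.integers(1, 100, 20), sorted(rng.random(20))[::-1])
            )
        ]
        kept = apply_threshold(uniques, 0.3)
        assert apply_threshold(kept, 0.3) == kept
        higher = apply_threshold(uniques, 0.5)
        assert set(u.seq for u in higher) <= set(u.seq for u in kept)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            apply_threshold([], 1.5)
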