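"""Artifact detection, classification, correction and window acceptance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herdstress.config import QCSettings
from herdstress.qc import (QCReport, accept_window, classify_errors,
                           correct_series, detect_errors, process_window)
from herdstress.simulate import ArtifactSpec, gen_ibi, inject_artifacts

QC = QCSettings()


def mk(values):
    from datetime import datetime

    from herdstress.ibi import IBISeries
    return IBISeries(cow="c", farm="f", session="s",
                     start=datetime(2013, 1, 7, 12),
                     intervals=np.asarray(values, dtype=float))


def naive_detect(x, thr=0.20):
    """Reference sequential detector (plain loop)."""
    flags = [False] * len(x)
    r = x[0]
    for i in range(1, len(x)):
        if abs(x[i] - r) > thr * r:
            flags[i] = True
        else:
            r = x[i]
    return np.array(flags)


class TestDetect:
    def test_single_wide_interval_flagged(self, make_series):
        ann = detect_errors(make_series([800, 1000, 810]))
        assert list(ann.flagged) == [False, True, False]

    def test_within_band_not_flagged(self, make_series):
        ann = detect_errors(make_series([800, 900, 810]))
        assert not ann.flagged.any()

    def test_constant_series_zero_flags(self, make_series):
        ann = detect_errors(make_series([750.0] * 50))
        assert ann.n_flagged == 0

    def test_too_short_series_rejected(self, make_series):
        with pytest.raises(Exception):
            detect_errors(make_series([800.0]))

    def test_flag_does_not_cascade_onto_normal_successor(self, make_series):
        # reference stays at the last accepted value, so 810 after the
        # 1620 artifact is judged against 800, not 1620
        ann = detect_errors(make_series([800, 1620, 810, 805]))
        assert list(ann.flagged) == [False, True, False, False]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=300, max_value=1500), min_size=2,
                    max_size=120))
    def test_fast_scan_matches_reference_loop(self, values):
        s = mk(values)
        np.testing.assert_array_equal(detect_errors(s).flagged,
                                      naive_detect(s.intervals))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_never_flags_series_within_ratio_band(self, seed):
        rng = np.random.default_rng(seed)
        x = [800.0]
        for _ in range(60):
            x.append(x[-1] * rng.uniform(0.85, 1.15))
        assert detect_errors(mk(x)).n_flagged == 0


class TestClassify:
    def test_wide_narrow_pair_is_type_2(self, make_series):
        s = make_series([800.0] * 6 + [1000.0, 620.0] + [810.0] * 5)
        ann = classify_errors(s, detect_errors(s), QC)
        assert list(ann.error_type[6:8]) == [2, 2]

    def test_narrow_wide_pair_is_type_3(self, make_series):
        s = make_series([800.0] * 6 + [620.0, 1000.0] + [810.0] * 5)
        ann = classify_errors(s, detect_errors(s), QC)
        assert list(ann.error_type[6:8]) == [3, 3]

    def test_single_overwide_is_type_4(self, make_series):
        s = make_series([800.0] * 6 + [1620.0] + [800.0] * 5)
        ann = classify_errors(s, detect_errors(s), QC)
        assert ann.error_type[6] == 4

    def test_double_narrow_is_type_5(self, make_series):
        s = make_series([800.0] * 6 + [400.0, 410.0] + [800.0] * 5)
        ann = classify_errors(s, detect_errors(s), QC)
        assert list(ann.error_type[6:8]) == [5, 5]

    def test_moderate_single_outlier_is_type_1(self, make_series):
        s = make_series([800.0] * 6 + [1100.0] + [800.0] * 5)
        ann = classify_errors(s, detect_errors(s), QC)
        assert ann.error_type[6] == 1

    def test_run_of_three_left_untyped(self, make_series):
        s = make_series([800.0] * 6 + [1300.0, 420.0, 1250.0] + [800.0] * 5)
        ann = classify_errors(s, detect_errors(s), QC)
        run = ann.error_type[6:9]
        assert (run == -1).all()


class TestCorrect:
    def test_merge_and_halve(self, make_series):
        s = make_series([800.0, 800.0, 800.0, 1000.0, 620.0, 810.0])
        corrected, _, _ = process_window(s, QC)
        np.testing.assert_allclose(corrected.intervals,
                                   [800, 800, 800, 810, 810, 810])
        assert corrected.duration_ms == pytest.approx(s.duration_ms, abs=1e-9)

    def test_split(self, make_series):
        s = make_series([800.0, 800.0, 800.0, 1620.0, 800.0])
        corrected, _, _ = process_window(s, QC)
        np.testing.assert_allclose(corrected.intervals,
                                   [800, 800, 800, 810, 810, 800])
        assert corrected.duration_ms == pytest.approx(s.duration_ms, abs=1e-9)

    def test_merge(self, make_series):
        s = make_series([800.0, 800.0, 800.0, 400.0, 410.0, 800.0])
        corrected, _, _ = process_window(s, QC)
        np.testing.assert_allclose(corrected.intervals,
                                   [800, 800, 800, 810, 800])
        assert corrected.duration_ms == pytest.approx(s.duration_ms, abs=1e-9)

    def test_interpolation_uses_flanking_unflagged(self, make_series):
        s = make_series([800.0, 800.0, 820.0, 1100.0, 840.0, 820.0])
        corrected, ann, _ = process_window(s, QC)
        assert ann.correction[3] == "interpolate"
        assert corrected.intervals[3] == pytest.approx((820.0 + 840.0) / 2)

    def test_boundary_flag_dropped(self, make_series):
        s = make_series([1500.0, 800.0, 800.0, 810.0])
        corrected, ann, _ = process_window(s, QC)
        # first interval cannot be flagged; a trailing artifact is dropped
        s2 = make_series([800.0, 800.0, 810.0, 1500.0])
        corrected2, ann2, _ = process_window(s2, QC)
        assert ann2.correction[3] == "drop"
        assert len(corrected2) == 3

    def test_inconsistent_annotation_raises(self, make_series):
        s = make_series([800.0, 800.0, 800.0])
        ann = detect_errors(s)
        ann.error_type[1] = 4  # typed but never flagged
        with pytest.raises(Exception):
            correct_series(s, ann, QC)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_types_2_to_5_conserve_duration(self, seed):
        rng = np.random.default_rng(seed)
        s = gen_ibi(8.0, 800, 330, seed=rng)
        cont, _ = inject_artifacts(
            s, ArtifactSpec(outlier_rate=0.0), seed=rng)
        corrected, ann, _ = process_window(cont, QC)
        if "drop" in ann.correction or (ann.error_type == -1).any():
            return  # boundary drops / untyped runs legitimately change duration
        assert corrected.duration_ms == pytest.approx(cont.duration_ms,
                                                      rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotence_on_accepted_windows(self, seed):
        """Re-running QC on a corrected accepted window finds no new
        pair/missed/spurious artifacts."""
        rng = np.random.default_rng(seed)
        s = gen_ibi(7.0, 780, 330, seed=rng)
        cont, _ = inject_artifacts(s, ArtifactSpec(), seed=rng)
        corrected, _, report = process_window(cont, QC)
        if not report.accepted:
            return
        ann2 = classify_errors(corrected, detect_errors(corrected), QC)
        assert not np.isin(ann2.error_type, [2, 3, 4, 5]).any()


class TestAcceptance:
    def _report(self, n, flagged, max_run):
        return QCReport(window_id="w", n_total=n, n_flagged=flagged,
                        max_consecutive=max_run, accepted=False)

    def test_low_rate_short_runs_accepted(self):
        assert accept_window(self._report(400, 10, 2), QC)  # 2.5%

    def test_rate_at_or_above_5pct_rejected(self):
        assert not accept_window(self._report(400, 25, 2), QC)  # 6.25%
        assert not accept_window(self._report(400, 20, 1), QC)  # exactly 5%

    def test_triple_run_rejected_regardless_of_rate(self):
        assert not accept_window(self._report(400, 3, 3), QC)  # 0.75%
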