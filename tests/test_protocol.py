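import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from openlook.errors import ConfigError
from openlook.looktime import SegmentationConfig, frames_to_looks
from openlook.protocol import (
    AOI,
    AOILabelSeries,
    Look,
    default_maap_protocol,
    labels_from_calibration,
    labels_from_coder_looks,
    protocol_from_dict,
    protocol_to_dict,
)
from openlook.quality import QualityConfig

from conftest import make_gaze_table


class TestDefaultProtocol:
    def test_trial_count_and_durations(self):
        p = default_maap_protocol()
        assert len(p.trials) == 24
        for t in p.trials:
            assert t.duration == pytest.approx(15.0)  # 3 s central + 12 s lateral
            assert t.lateral_onset - t.central_onset == pytest.approx(3.0)

    def test_calibration_sequence_repeats_once(self):
        p = default_maap_protocol()
        order = [g.location for g in p.calibration]
        base = [AOI.CENTER, AOI.LEFT, AOI.CENTER, AOI.RIGHT]
        assert order == base + base
        assert all(g.duration_ms == 1500.0 for g in p.calibration)

    def test_blocks_alternate_conditions(self):
        p = default_maap_protocol()
        conditions = [t.condition for t in p.trials]
        assert conditions[:6] == ["social"] * 6
        assert conditions[6:12] == ["nonsocial"] * 6
        assert conditions[12:18] == ["social"] * 6

    def test_sync_side_counterbalanced_within_block(self):
        p = default_maap_protocol()
        for b in range(4):
            sides = [t.sync_side for t in p.trials[b * 6 : (b + 1) * 6]]
            assert sides.count(AOI.LEFT) == 3
            assert sides.count(AOI.RIGHT) == 3

    def test_events_nonoverlapping_and_ordered(self):
        p = default_maap_protocol()
        spans = [(g.onset, g.offset) for g in p.calibration] + [
            (t.onset, t.offset) for t in p.trials
        ]
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert b0 >= a1 - 1e-9

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ConfigError):
            default_maap_protocol(central_duration=0.0)

    def test_json_roundtrip(self):
        p = default_maap_protocol(n_trials=4, block_size=2)
        q = protocol_from_dict(protocol_to_dict(p))
        assert q.trials == p.trials
        assert q.calibration == p.calibration


class TestCalibrationLabels:
    def test_window_membership_and_trim(self):
        p = default_maap_protocol()
        n = 200
        table = make_gaze_table([0.9] * n, fps=10.0)
        labels = labels_from_calibration(p, table, trim_ms=300.0, cfg=QualityConfig())
        # second getter (LEFT) spans [1.5, 3.0); frames at 2.0-2.9 s are inside
        assert labels.codes[22] == AOI.LEFT
        # first 300 ms of that window (1.5-1.8 s) stays unlabeled
        assert labels.codes[15] == AOI.UNLABELED
        assert labels.codes[16] == AOI.UNLABELED
        # frames after the last getter are outside every window
        assert labels.codes[-1] == AOI.UNLABELED
        assert labels.source == "calibration"

    def test_unusable_frames_unlabeled_only_with_quality_config(self):
        p = default_maap_protocol()
        n = 150
        conf = [0.1] * n
        table = make_gaze_table(conf, fps=10.0)
        gated = labels_from_calibration(p, table, cfg=QualityConfig())
        ungated = labels_from_calibration(p, table, cfg=None)
        assert (gated.codes == AOI.UNLABELED).all()
        assert (ungated.codes != AOI.UNLABELED).any()

    def test_every_label_matches_covering_getter(self):
        p = default_maap_protocol()
        table = make_gaze_table([0.9] * 130, fps=10.0)
        labels = labels_from_calibration(p, table, trim_ms=0.0, cfg=None)
        ts = table.timestamps
        for i, code in enumerate(labels.codes):
            covering = [g for g in p.calibration if g.onset <= ts[i] < g.offset]
            if covering:
                assert code == covering[0].location
            else:
                assert code == AOI.UNLABELED

    def test_table_before_calibration_is_alignment_error(self):
        from openlook.errors import AlignmentError

        p = default_maap_protocol()
        table = make_gaze_table([])
        with pytest.raises(AlignmentError):
            labels_from_calibration(p, table)


class TestCoderLooks:
    def test_one_second_look_at_10fps(self):
        table = make_gaze_table([1.0] * 15, fps=10.0)
        labels = labels_from_coder_looks([Look(AOI.LEFT, 0.0, 1.0)], table)
        assert (labels.codes[:10] == AOI.LEFT).all()
        assert (labels.codes[10:] == AOI.UNLABELED).all()

    def test_empty_log_all_unlabeled(self):
        table = make_gaze_table([1.0] * 5)
        labels = labels_from_coder_looks([], table)
        assert (labels.codes == AOI.UNLABELED).all()

    def test_shared_boundary_not_double_labeled(self):
        table = make_gaze_table([1.0] * 20, fps=10.0)
        looks = [Look(AOI.LEFT, 0.0, 1.0), Look(AOI.RIGHT, 1.0, 2.0)]
        labels = labels_from_coder_looks(looks, table)
        assert labels.codes[9] == AOI.LEFT
        assert labels.codes[10] == AOI.RIGHT  # frame at exactly 1.0 s

    def test_overlapping_looks_rejected(self):
        table = make_gaze_table([1.0] * 20, fps=10.0)
        looks = [Look(AOI.LEFT, 0.0, 1.0), Look(AOI.RIGHT, 0.5, 2.0)]
        with pytest.raises(ConfigError, match="overlap"):
            labels_from_coder_looks(looks, table)

    @given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=60))
    def test_roundtrip_with_segmentation(self, codes):
        """looks -> frame labels inverts segmentation on OFF-free series."""
        fps = 10.0
        series = AOILabelSeries(np.array(codes, dtype=np.int8), source="truth")
        looks = frames_to_looks(
            series, fps, SegmentationConfig(min_look_ms=0.0, bridge_gap_frames=0)
        )
        table = make_gaze_table([1.0] * len(codes), fps=fps)
        back = labels_from_coder_looks(looks, table)
        np.testing.assert_array_equal(back.codes, series.codes)


def test_label_series_csv_roundtrip(tmp_path):
    series = AOILabelSeries.from_names(
        ["LEFT", "OFF", "CENTER", "UNLABELED", "RIGHT"], source="coder"
    )
    path = tmp_path / "labels.csv"
    series.write_csv(path)
    back = AOILabelSeries.read_csv(path)
    np.testing.assert_array_equal(back.codes, series.codes)
    assert back.source == "coder"
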