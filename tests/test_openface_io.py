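import numpy as np
import pandas as pd
import pytest

from openlook.errors import ParseError, SchemaError
from openlook.openface_io import (
    column_groups,
    feature_columns,
    read_openface_csv,
    write_openface_csv,
)
from openlook.simulate import simulate_session

from conftest import make_gaze_table


@pytest.mark.parametrize(
    "group,width",
    [
        ("gaze", 11),
        ("eye_landmarks_2d", 112),
        ("eye_landmarks_3d", 168),
        ("pose", 6),
        ("face_landmarks_2d", 136),
        ("face_landmarks_3d", 204),
        ("shape_params", 40),
        ("action_units", 35),
    ],
)
def test_group_widths(group, width):
    assert len(column_groups(group)) == width


def test_groups_disjoint_and_cover_all_features():
    groups = column_groups()
    all_cols = [c for cols in groups.values() for c in cols]
    assert len(all_cols) == len(set(all_cols)) == 712
    assert feature_columns() == all_cols


def test_unknown_group_rejected():
    with pytest.raises(KeyError, match="unknown feature group"):
        column_groups("eyebrows")


def test_two_row_fixture_mean_confidence(tmp_path):
    table = make_gaze_table([0.9, 0.8])
    path = tmp_path / "two.csv"
    write_openface_csv(table, path)
    back = read_openface_csv(path)
    assert back.n_frames == 2
    assert back.confidence.mean() == pytest.approx(0.85)


def test_roundtrip_preserves_fields(tmp_path, short_session):
    table = short_session[0]
    path = tmp_path / "session.csv"
    write_openface_csv(table, path)
    back = read_openface_csv(path, fps=table.fps)
    assert back.n_frames == table.n_frames
    pd.testing.assert_frame_equal(back.data, table.data, check_dtype=False, atol=1e-9)


def test_roundtrip_preserves_occlusion_flags(tmp_path, short_session):
    table = short_session[0]
    assert (table.success == 0).any(), "fixture should contain occluded frames"
    path = tmp_path / "occ.csv"
    write_openface_csv(table, path)
    back = read_openface_csv(path)
    np.testing.assert_array_equal(back.success, table.success)


def test_empty_table_roundtrip(tmp_path):
    table = make_gaze_table([])
    path = tmp_path / "empty.csv"
    write_openface_csv(table, path)
    assert read_openface_csv(path).n_frames == 0


def test_frame_column_rebased_to_zero(tmp_path):
    table = make_gaze_table([0.9, 0.9, 0.9])
    path = tmp_path / "frames.csv"
    write_openface_csv(table, path)
    raw = pd.read_csv(path)
    assert raw["frame"].tolist() == [1, 2, 3]  # on-disk dialect is 1-based
    back = read_openface_csv(path)
    assert back.data["frame"].tolist() == [0, 1, 2]


def test_header_whitespace_stripped(tmp_path):
    table = make_gaze_table([0.5, 0.6])
    path = tmp_path / "padded.csv"
    write_openface_csv(table, path)
    text = path.read_text()
    header, rest = text.split("\n", 1)
    padded = ", ".join(h for h in header.split(","))
    path.write_text(padded + "\n" + rest)
    back = read_openface_csv(path)
    assert back.confidence.tolist() == [0.5, 0.6]


def test_missing_confidence_is_schema_error(tmp_path):
    table = make_gaze_table([0.9, 0.8])
    path = tmp_path / "broken.csv"
    write_openface_csv(table, path)
    df = pd.read_csv(path).drop(columns=["confidence"])
    df.to_csv(path, index=False)
    with pytest.raises(SchemaError, match="confidence"):
        read_openface_csv(path)


def test_non_numeric_cell_reports_row(tmp_path):
    table = make_gaze_table([0.9, 0.8])
    path = tmp_path / "nonnum.csv"
    write_openface_csv(table, path)
    df = pd.read_csv(path).astype(object)
    df.loc[1, "gaze_0_x"] = "oops"
    df.to_csv(path, index=False)
    with pytest.raises(ParseError, match="row 2"):
        read_openface_csv(path)


def test_gaze_average_derived_when_absent(tmp_path):
    table = make_gaze_table([1.0], yaw=[0.2])
    path = tmp_path / "noavg.csv"
    write_openface_csv(table, path)
    df = pd.read_csv(path).drop(columns=["gaze_avg_x", "gaze_avg_y", "gaze_avg_z"])
    df.to_csv(path, index=False)
    back = read_openface_csv(path)
    avg = back.data[["gaze_avg_x", "gaze_avg_y", "gaze_avg_z"]].to_numpy()[0]
    assert np.linalg.norm(avg) == pytest.approx(1.0, abs=1e-9)
    # both eyes identical here, so the average equals either eye vector
    np.testing.assert_allclose(avg, back.data[["gaze_0_x", "gaze_0_y", "gaze_0_z"]].to_numpy()[0])


def test_unit_norm_invariant_checked():
    table = make_gaze_table([1.0, 1.0], yaw=[0.0, 0.1])
    table.validate_records()  # passes on unit vectors, e.g. (0, 0, -1)
    bad = table.data.copy()
    bad.loc[0, "gaze_0_x"] = 5.0
    from openlook.openface_io import SessionTable

    broken = SessionTable(data=bad, fps=10.0)
    with pytest.raises(SchemaError, match="norm"):
        broken.validate_records()


def test_timestamps_must_be_nondecreasing():
    table = make_gaze_table([1.0, 1.0, 1.0])
    df = table.data.copy()
    df.loc[2, "timestamp"] = 0.0
    from openlook.openface_io import SessionTable

    with pytest.raises(SchemaError, match="nondecreasing"):
        SessionTable(data=df)


def test_fps_estimated_from_timestamps():
    table = make_gaze_table([1.0] * 5, fps=25.0)
    from openlook.openface_io import SessionTable

    est = SessionTable(data=table.data.copy())
    assert est.fps == pytest.approx(25.0)


def test_record_accessor_shapes(short_session):
    rec = short_session[0].record(0)
    assert rec.eye_landmarks_2d.shape == (56, 2)
    assert rec.face_landmarks_3d.shape == (68, 3)
    assert rec.shape_params.shape == (40,)
    assert rec.action_units.shape == (35,)
    assert rec.gaze_avg.shape == (3,)
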