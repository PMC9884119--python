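"""Measurement, QC filtering, region restriction and table round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from embryoquant import (Calibration, ImageStack, LabelVolume, QCThresholds,
                         apply_region, export_table, measure_nuclei,
                         qc_filter, read_table)
from embryoquant.synthetic import (NoiseParams, SyntheticEmbryoSpec,
                                   render_stack, truth_labels, embryonic_roi)

CAL = Calibration(0.5, 2.0)


def _toy_stack_and_labels():
    """One 10-voxel nucleus with channel value 5 everywhere."""
    lab = np.zeros((2, 4, 4), dtype=np.int32)
    lab[0, 0, :4] = 1
    lab[1, 0, :4] = 1
    lab[0, 1, :2] = 1
    data = np.zeros((2, 2, 4, 4), dtype=np.uint8)
    data[:, 0] = 80  # DNA channel
    data[:, 1] = 5
    stack = ImageStack(data, ("DAPI", "marker"), CAL)
    return LabelVolume(lab, CAL), stack


class TestMeasureNuclei:
    def test_mean_and_integrated_density_on_toy_object(self):
        labels, stack = _toy_stack_and_labels()
        table = measure_nuclei(labels, stack)
        assert len(table) == 1
        assert table["voxel_count"].iloc[0] == 10
        assert table["mean_marker"].iloc[0] == 5.0
        assert table["intden_marker"].iloc[0] == 50.0
        assert table["volume_um3"].iloc[0] == pytest.approx(10 * 0.5 * 0.5 * 2.0)

    def test_empty_labels_give_empty_table(self):
        labels, stack = _toy_stack_and_labels()
        labels.data[:] = 0
        assert len(measure_nuclei(labels, stack)) == 0

    def test_shape_mismatch_rejected(self):
        labels, stack = _toy_stack_and_labels()
        bad = LabelVolume(np.zeros((3, 4, 4), dtype=np.int32), CAL)
        with pytest.raises(ValueError):
            measure_nuclei(bad, stack)

    def test_intden_equals_mean_times_count_exactly(self, small_segmented):
        stack, _, labels, _ = small_segmented
        table = measure_nuclei(labels, stack)
        for name in stack.channel_names:
            lhs = table[f"intden_{name}"].to_numpy()
            rhs = (table[f"mean_{name}"] * table["voxel_count"]).to_numpy()
            assert np.array_equal(lhs, rhs)

    def test_noise_free_intden_conserves_ground_truth_signal(self):
        """Measured on the true support with noise off, integrated density
        recovers the generator's total signal up to quantisation."""
        spec = SyntheticEmbryoSpec(
            n_epi=2, n_pre=0, n_te=0, slice_shape=(128, 128),
            noise=NoiseParams(0.0, 0.0), background=0.0, seed=21,
        )
        stack, truth = render_stack(spec)
        labels = LabelVolume(truth_labels(spec, truth), spec.calibration)
        table = measure_nuclei(labels, stack).sort_values("nucleus_id")
        for row, (_, t) in zip(table.itertuples(), truth.iterrows()):
            for name in spec.channels:
                measured = getattr(row, f"intden_{name}")
                assert abs(measured - t[f"total_{name}"]) <= 0.5 * row.voxel_count

    def test_total_intden_bounded_by_channel_total(self, small_segmented):
        stack, _, labels, _ = small_segmented
        table = measure_nuclei(labels, stack)
        for name in stack.channel_names:
            total = stack.channel(name).astype(float).sum()
            assert table[f"intden_{name}"].sum() <= total


class TestQCFilter:
    THR = QCThresholds()  # (2, 10) DNA mean, (150, 700) volume

    def _table(self, rows):
        return pd.DataFrame(rows, columns=["dapi_mean_qc", "volume_um3"])

    @pytest.mark.parametrize("dapi,volume,kept", [
        (5.0, 300.0, True),
        (1.0, 300.0, False),   # below DNA lower limit
        (5.0, 800.0, False),   # above volume upper limit
        (2.0, 300.0, False),   # DNA boundary value removed (open interval)
        (10.0, 300.0, False),
        (5.0, 150.0, False),   # volume boundary removed
        (5.0, 700.0, False),
        (2.0001, 150.0001, True),
        (9.9999, 699.9999, True),
    ])
    def test_open_interval_windows(self, dapi, volume, kept):
        out = qc_filter(self._table([(dapi, volume)]), self.THR)
        assert len(out) == (1 if kept else 0)

    def test_set_application(self):
        table = self._table([(5, 300), (1, 300), (5, 800)])
        out = qc_filter(table, self.THR)
        assert len(out) == 1
        assert out["dapi_mean_qc"].iloc[0] == 5 and out["volume_um3"].iloc[0] == 300

    @given(st.lists(st.tuples(st.floats(0, 15), st.floats(0, 1000)), max_size=30))
    def test_idempotent_and_subset(self, rows):
        table = self._table(rows)
        once = qc_filter(table, self.THR)
        twice = qc_filter(once, self.THR)
        pd.testing.assert_frame_equal(once, twice)
        assert set(once.index) <= set(table.index)

    def test_missing_column_rejected(self):
        with pytest.raises(KeyError):
            qc_filter(pd.DataFrame({"volume_um3": [1.0]}), self.THR)


class TestApplyRegion:
    def test_all_true_and_all_false_masks(self, small_segmented, small_spec):
        stack, _, labels, _ = small_segmented
        table = measure_nuclei(labels, stack)
        roi = np.ones((stack.n_z, *stack.slice_shape), dtype=bool)
        assert apply_region(table, roi, stack.calibration)["in_region"].all()
        assert not apply_region(table, ~roi, stack.calibration)["in_region"].any()

    def test_hemisphere_roi_keeps_icm_drops_mural_te(self, small_segmented,
                                                     small_spec):
        from conftest import match_detections
        stack, truth, labels, _ = small_segmented
        table = measure_nuclei(labels, stack)
        table = apply_region(table, embryonic_roi(small_spec), stack.calibration)
        pairs, *_ = match_detections(truth, table, small_spec.nucleus_radius_um)
        in_region = dict(
            (ti, bool(table["in_region"].iloc[mi])) for ti, mi in pairs
        )
        axis = small_spec.embryonic_axis
        rel = truth[["x_um", "y_um", "z_um"]].to_numpy() - small_spec.centre_um
        mural_te = (rel @ axis < 0) & (truth["lineage"] == "TE").to_numpy()
        icm = (truth["lineage"] != "TE").to_numpy()
        matched_icm = [v for ti, v in in_region.items() if icm[ti]]
        matched_mural = [v for ti, v in in_region.items() if mural_te[ti]]
        assert matched_icm and all(matched_icm)
        assert matched_mural and sum(matched_mural) <= len(matched_mural) / 2


class TestExportTable:
    def test_round_trip_preserves_values(self, tmp_path, small_segmented):
        stack, _, labels, _ = small_segmented
        table = measure_nuclei(labels, stack, embryo_id="e1", stage="E3.5")
        path = tmp_path / "t.csv"
        export_table(table, path, channel_names=stack.channel_names)
        back = read_table(path)
        assert list(back.columns) == list(table.columns)
        for col in table.columns:
            if table[col].dtype.kind == "f":
                assert np.array_equal(back[col].to_numpy(), table[col].to_numpy())
            else:
                assert (back[col].astype(str) == table[col].astype(str)).all() or \
                    (back[col] == table[col]).all()

    def test_empty_table_writes_header_only(self, tmp_path):
        from embryoquant.quantify import _empty_table
        path = tmp_path / "empty.csv"
        export_table(_empty_table(("DAPI",)), path, channel_names=("DAPI",))
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("embryo_id,nucleus_id,x_um")

    def test_three_records_write_four_lines(self, tmp_path):
        table = pd.DataFrame({
            "embryo_id": ["e"] * 3, "nucleus_id": [1, 2, 3],
            "x_um": [0.5, 1.5, 2.5], "y_um": [0.0] * 3, "z_um": [0.0] * 3,
            "voxel_count": [5, 6, 7], "volume_um3": [2.5, 3.0, 3.5],
            "mean_DAPI": [1.0] * 3, "intden_DAPI": [5.0, 6.0, 7.0],
            "dapi_mean_qc": [4.0] * 3, "in_region": [True] * 3,
            "stage": ["E3.5"] * 3, "genotype": ["WT"] * 3,
        })
        path = tmp_path / "t.csv"
        export_table(table, path)
        assert len(path.read_text().strip().splitlines()) == 4
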