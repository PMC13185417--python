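"""Per-cell quantification stages, classification windows, summaries."""

import numpy as np
import pytest

from g4quant.foci import (
    CellQuant,
    ExperimentMismatchError,
    FociParams,
    FociQuantError,
    cells_to_frame,
    classify_and_filter,
    clear_outside_roi,
    estimate_foci_threshold,
    flag_outliers,
    label_components,
    quantify_cell,
    segment_foci,
    segment_nucleus,
    subtract_background,
    summarize_condition,
)
from g4quant.imaging import CellROI, ImageStack
from g4quant.simulate import SimulationConfig, simulate_cell_stack

from conftest import quantify_ready_cell


def _stack(foci=None, dapi=None, shape=(5, 16, 16)):
    ch = {
        "foci": np.full(shape, 0.0) if foci is None else foci,
        "dapi": np.full(shape, 1.0) if dapi is None else dapi,
    }
    return ImageStack(channels=ch)


class TestSubtractBackground:
    def test_constant_minus_itself_is_zero(self):
        s = _stack(foci=np.full((5, 16, 16), 100.0))
        out = subtract_background(s, 100.0)
        assert np.all(out.channels["foci"] == 0.0)

    def test_zero_background_is_identity(self):
        s = _stack(foci=np.random.default_rng(0).uniform(0, 50, (5, 16, 16)))
        out = subtract_background(s, 0.0)
        assert np.array_equal(out.channels["foci"], s.channels["foci"])

    def test_region_estimate_recovers_planted_level(self):
        stack, truth = simulate_cell_stack(SimulationConfig(seed=13))
        out = subtract_background(stack, ~truth.cell_mask)
        est = out.provenance["background_estimate"]
        assert abs(est - truth.background_level) < 0.5

    def test_empty_region_rejected(self):
        s = _stack()
        with pytest.raises(FociQuantError, match="empty"):
            subtract_background(s, np.zeros((5, 16, 16), bool))


class TestClearOutsideRoi:
    def test_whole_field_roi_is_identity(self):
        s = _stack(foci=np.random.default_rng(1).uniform(0, 9, (5, 16, 16)))
        roi = CellROI("all", np.ones((5, 16, 16), bool))
        out = clear_outside_roi(s, roi)
        assert np.array_equal(out.channels["foci"], s.channels["foci"])

    def test_outside_voxels_are_zero_in_all_channels(self):
        s = _stack(
            foci=np.random.default_rng(2).uniform(1, 9, (5, 16, 16)),
            dapi=np.random.default_rng(3).uniform(1, 9, (5, 16, 16)),
        )
        mask = np.zeros((5, 16, 16), bool)
        mask[:, 4:12, 4:12] = True
        out = clear_outside_roi(s, CellROI("c", mask))
        for ch in out.channels:
            assert np.all(out.channels[ch][~mask] == 0.0)
            assert np.all(out.channels[ch][mask] > 0.0)

    def test_empty_roi_rejected_at_construction(self):
        from g4quant.imaging import ImageStackError

        with pytest.raises(ImageStackError, match="empty"):
            CellROI("void", np.zeros((5, 16, 16), bool))

    def test_shape_mismatch_rejected(self):
        s = _stack()
        roi = CellROI("c", np.ones((5, 8, 8), bool))
        with pytest.raises(FociQuantError, match="shape"):
            clear_outside_roi(s, roi)


class TestSegmentNucleus:
    def test_recovers_planted_ellipsoid(self):
        stack, truth = simulate_cell_stack(SimulationConfig(seed=21))
        mask = segment_nucleus(stack, truth.roi())
        inter = (mask & truth.nucleus_mask).sum()
        union = (mask | truth.nucleus_mask).sum()
        assert inter / union >= 0.95

    def test_uniform_dapi_rejected(self):
        s = _stack(dapi=np.full((5, 16, 16), 7.0))
        with pytest.raises(FociQuantError, match="constant"):
            segment_nucleus(s)

    def test_keeps_only_largest_component(self):
        dapi = np.zeros((5, 16, 16))
        dapi[1:4, 2:7, 2:7] = 100.0  # larger blob
        dapi[2:3, 10:12, 10:12] = 100.0  # smaller blob
        mask = segment_nucleus(_stack(dapi=dapi))
        assert mask[2, 4, 4] and not mask[2, 10, 10]
        labels, n = label_components(mask, 26)
        assert n == 1


class TestSegmentFoci:
    def test_single_voxel_component(self):
        foci = np.zeros((5, 16, 16))
        foci[2, 8, 8] = 50.0
        params = FociParams(threshold=10.0, experiment_id="e1")
        labels, n = segment_foci(_stack(foci=foci), params)
        assert n == 1 and (labels > 0).sum() == 1

    def test_corner_contact_is_connected_at_26_not_6(self):
        foci = np.zeros((5, 16, 16))
        foci[2, 8, 8] = 50.0
        foci[3, 9, 9] = 50.0  # touches only at a corner
        p26 = FociParams(threshold=10.0, experiment_id="e1", connectivity=26)
        p6 = FociParams(threshold=10.0, experiment_id="e1", connectivity=6)
        assert segment_foci(_stack(foci=foci), p26)[1] == 1
        assert segment_foci(_stack(foci=foci), p6)[1] == 2

    def test_params_frozen_per_experiment(self):
        params = FociParams(threshold=10.0, experiment_id="exp1")
        s = _stack(foci=np.zeros((5, 16, 16)))
        segment_foci(s, params, experiment_id="exp1")  # same experiment: fine
        with pytest.raises(ExperimentMismatchError):
            segment_foci(s, params, experiment_id="exp2")
        params.allow_reuse = True
        segment_foci(s, params, experiment_id="exp2")  # explicit override

    def test_threshold_below_background_rejected(self):
        with pytest.raises(FociQuantError, match="below background"):
            FociParams(threshold=5.0, experiment_id="e", background_mean=10.0)

    def test_threshold_estimated_from_nt_fields(self):
        stacks = []
        for seed in (1, 2):
            stack, truth = simulate_cell_stack(SimulationConfig(seed=seed))
            stacks.append(subtract_background(stack, ~truth.cell_mask))
        params = estimate_foci_threshold(stacks, experiment_id="e1", k=3.0)
        assert params.threshold > params.background_mean
        assert params.experiment_id == "e1"


def _labels_of_sizes(compartment_sizes):
    """Build a label map with (size, in_nucleus) components, plus the nucleus mask.

    Each component fills a prefix of a private 2-row slab (rows 3i, 3i+1)
    on the nuclear (x < 58) or cytoplasmic (x >= 60) side, in an order that
    keeps every prefix 26-connected; slabs are separated by an empty row.
    """
    shape = (5, 64, 120)
    labels = np.zeros(shape, dtype=int)
    nucleus = np.zeros(shape, bool)
    nucleus[:, :, :60] = True
    for i, (size, in_nucleus) in enumerate(compartment_sizes, start=1):
        assert size <= 2 * 5 * 58, "component too large for the slab layout"
        x0 = 0 if in_nucleus else 60
        v = 0
        for y_off in (0, 1):
            for z in range(5):
                for x in range(58):
                    if v == size:
                        break
                    labels[z, 3 * i + y_off, x0 + x] = i
                    v += 1
    return labels, len(compartment_sizes), nucleus


class TestClassifyAndFilter:
    @pytest.mark.parametrize(
        "size,in_nucleus,expect",
        [
            (2, True, None),  # below nuclear minimum -> discarded
            (3, True, "nuclear"),
            (100, True, "nuclear"),
            (101, True, "nucleolar"),
            (150, True, "nucleolar"),
            (19, False, None),  # below cytoplasmic minimum
            (20, False, "cytoplasmic"),
            (100, False, "cytoplasmic"),
            (101, False, None),  # oversized cytoplasmic -> discarded
        ],
    )
    def test_size_windows(self, size, in_nucleus, expect):
        labels, n, nucleus = _labels_of_sizes([(size, in_nucleus)])
        kept, discarded = classify_and_filter(labels, n, nucleus, mode="tasq")
        if expect is None:
            assert kept == [] and len(discarded) == 1
        else:
            assert len(kept) == 1 and kept[0].compartment == expect
            assert kept[0].voxel_count == size

    def test_partition_every_component_accounted(self):
        sizes = [(2, True), (50, True), (200, True), (10, False), (30, False), (400, False)]
        labels, n, nucleus = _labels_of_sizes(sizes)
        kept, discarded = classify_and_filter(labels, n, nucleus, mode="tasq")
        assert len(kept) + len(discarded) == n
        kept_labels = {f.label for f in kept} | {d["label"] for d in discarded}
        assert kept_labels == set(range(1, n + 1))

    def test_gh2ax_mode_nucleus_restricted(self):
        sizes = [(1, True), (2, True), (50, True), (30, False)]
        labels, n, nucleus = _labels_of_sizes(sizes)
        kept, discarded = classify_and_filter(labels, n, nucleus, mode="gh2ax")
        assert sorted(f.voxel_count for f in kept) == [2, 50]
        reasons = {d["reason"] for d in discarded}
        assert "outside nucleus" in reasons and "below minimum size" in reasons

    def test_gh2ax_min_size_monotone(self):
        sizes = [(s, True) for s in (1, 2, 3, 5, 8)]
        labels, n, nucleus = _labels_of_sizes(sizes)
        counts = [
            len(classify_and_filter(labels, n, nucleus, "gh2ax", gh2ax_min_voxels=m)[0])
            for m in (1, 2, 4, 6, 9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(FociQuantError, match="shape"):
            classify_and_filter(np.zeros((5, 8, 8), int), 0, np.zeros((5, 9, 9), bool))


class TestQuantifyCell:
    def test_exact_counts_for_separable_cell(self, separable_cell):
        stack, truth, params = separable_cell
        q = quantify_cell(stack, truth.roi(), params, experiment_id="exp")
        assert q.nuclear_count == 10
        assert q.cytoplasmic_count == 5
        assert q.nucleolar_count >= 2
        assert sorted(f.voxel_count for f in q.foci if f.compartment == "nuclear") == [
            3, 5, 8, 12, 20, 30, 45, 60, 80, 100,
        ]

    def test_zero_foci_gives_zero_counts(self):
        cfg = SimulationConfig(seed=2, nuclear_sizes=[], cytoplasmic_sizes=[])
        stack, truth, params = quantify_ready_cell(cfg)
        q = quantify_cell(stack, truth.roi(), params, experiment_id="exp")
        assert q.nuclear_count == 0 and q.cytoplasmic_count == 0
        assert q.nucleolar_count >= 2  # nucleoli are still there

    def test_large_nuclear_object_lands_in_nucleolar_list(self):
        cfg = SimulationConfig(seed=6, nuclear_sizes=[200], cytoplasmic_sizes=[])
        stack, truth, params = quantify_ready_cell(cfg)
        q = quantify_cell(stack, truth.roi(), params, experiment_id="exp")
        assert q.nuclear_count == 0
        assert 200 in [f.voxel_count for f in q.foci if f.compartment == "nucleolar"]

    def test_error_annotated_with_roi_id(self):
        s = _stack(dapi=np.full((5, 16, 16), 3.0), foci=np.zeros((5, 16, 16)))
        roi = CellROI("cell-7", np.ones((5, 16, 16), bool))
        params = FociParams(threshold=1.0, experiment_id="e")
        with pytest.raises(FociQuantError, match="cell-7"):
            quantify_cell(s, roi, params)


def _fake_cell(roi_id, volume=500, intensity=5e5, nucleoli=2):
    foci = []
    shape = (5, 8, 8)
    q = CellQuant(
        roi_id=roi_id,
        nucleus_mask=np.ones(shape, bool),
        nucleolus_mask=np.zeros(shape, bool),
        foci=foci,
        discarded=[],
        dapi_volume=volume,
        dapi_intensity=intensity,
    )
    from g4quant.foci import Focus

    for i in range(nucleoli):
        foci.append(Focus(i + 1, 150, "nucleolar", 1.0, 1.0, (0, 0, 0, 1, 1, 1), (0, 0, 0)))
    return q


class TestFlagOutliers:
    def test_identical_cells_unflagged(self):
        cells = [_fake_cell(str(i)) for i in range(10)]
        out = flag_outliers(cells)
        assert not any(c.excluded for c in out)

    def test_zero_dapi_cell_flagged(self):
        rng = np.random.default_rng(0)
        cells = [
            _fake_cell(str(i), volume=int(rng.normal(500, 20)), intensity=rng.normal(5e5, 2e4))
            for i in range(20)
        ]
        cells.append(_fake_cell("dead", volume=480, intensity=0.0))
        out = flag_outliers(cells)
        assert out[-1].excluded and "DAPI missing or lowered" in out[-1].qc_flags

    def test_dim_dapi_cell_flagged(self):
        rng = np.random.default_rng(1)
        cells = [
            _fake_cell(str(i), intensity=rng.normal(5e5, 1e4)) for i in range(20)
        ]
        cells.append(_fake_cell("dim", intensity=5e4))  # 10x dimmer
        assert flag_outliers(cells)[-1].excluded

    def test_missing_nucleoli_flagged_in_tasq_mode(self):
        cells = [_fake_cell(str(i)) for i in range(9)] + [_fake_cell("x", nucleoli=0)]
        out = flag_outliers(cells, mode="tasq")
        assert out[-1].excluded and "nucleoli not segmented" in out[-1].qc_flags
        cells2 = [_fake_cell(str(i), nucleoli=0) for i in range(5)]
        assert not any(c.excluded for c in flag_outliers(cells2, mode="gh2ax"))

    def test_few_cells_warns_and_skips(self):
        cells = [_fake_cell("a"), _fake_cell("b", intensity=0.0)]
        with pytest.warns(UserWarning, match="fewer than 5"):
            out = flag_outliers(cells)
        assert not any(c.excluded for c in out)


class TestSummaries:
    def _frame(self, rows):
        import pandas as pd

        return pd.DataFrame(rows, columns=["condition", "experiment", "value"])

    def test_condition_identical_to_nt(self):
        f = self._frame(
            [("NT", "e1", 4), ("NT", "e2", 4), ("drug", "e1", 4), ("drug", "e2", 4)]
        )
        s = {x.condition: x for x in summarize_condition(f)}
        assert s["drug"].fold_change == pytest.approx(1.0)
        assert s["drug"].delta == pytest.approx(0.0)
        assert s["NT"].fold_change == pytest.approx(1.0)

    def test_experiment_level_averaging(self):
        # experiment means 2 and 4 -> across-experiment mean 3, even with
        # unbalanced cell counts
        f = self._frame(
            [("NT", "e1", 1), ("NT", "e2", 1)]
            + [("drug", "e1", 2)] * 10
            + [("drug", "e2", 4)] * 2
        )
        s = {x.condition: x for x in summarize_condition(f)}
        assert s["drug"].mean == pytest.approx(3.0)
        assert s["drug"].fold_change == pytest.approx(3.0)

    def test_zero_nt_mean_leaves_fold_missing(self):
        f = self._frame([("NT", "e1", 0), ("NT", "e2", 0), ("drug", "e1", 2), ("drug", "e2", 2)])
        with pytest.warns(UserWarning, match="fold change undefined"):
            s = {x.condition: x for x in summarize_condition(f)}
        assert s["drug"].fold_change is None
        assert s["drug"].delta == pytest.approx(2.0)

    def test_missing_nt_condition_rejected(self):
        f = self._frame([("drug", "e1", 2)])
        with pytest.raises(FociQuantError, match="NT"):
            summarize_condition(f)

    def test_excluded_cells_dropped_from_frame(self):
        a, b = _fake_cell("a"), _fake_cell("b")
        b.excluded = True
        frame = cells_to_frame({("NT", "e1"): [a, b]}, metric="nuclear")
        assert len(frame) == 1
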