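import numpy as np
import pytest

import codeit as ci
from codeit.errors import CodeitError, MultipleDonorsError
from oracles import per_cell_transfer_oracle, pseudo_donor_oracle

VS = (1.01, 0.445, 0.445)


def _stack(arr, vs=VS):
    return ci.VoxelStack(np.asarray(arr, dtype=np.uint8), vs)


def records_by_label(result):
    return {r.cell_label: r for r in result.records}


class TestDetectDonor:
    def test_recognises_painted_donor(self, painted, small_lawn, cfg):
        channels, gt, _ = painted
        donor = ci.detect_donor(channels["did"], None, small_lawn.labels, cfg)
        assert not donor.is_control
        assert donor.donor_cell_label == gt.donor_label
        # donor mask covers the donor cell and the dilation adds exactly
        # a one-voxel rim
        from scipy.ndimage import binary_dilation

        np.testing.assert_array_equal(
            donor.dilated_mask, binary_dilation(donor.mask, np.ones((3, 3, 3)))
        )
        assert np.all(donor.mask[small_lawn.labels == gt.donor_label])

    def test_small_bright_speck_discarded(self, small_lawn, cfg):
        """A supra-threshold object under 1,000 um^3 is not a donor."""
        did = small_lawn.channels["did"].intensities.copy()
        # ~500 um^3 bright blob: 500 / 0.2 ~ 2500 voxels = 4 x 25 x 25
        did[4:8, 40:65, 40:65] = 255
        vol_um3 = 4 * 25 * 25 * ci.voxel_volume(small_lawn.channels["did"])
        assert vol_um3 < cfg.donor_min_volume
        donor = ci.detect_donor(_stack(did), None, small_lawn.labels, cfg)
        assert donor.is_control

    def test_control_stack_gets_pseudo_donor(self, small_lawn, cfg):
        donor = ci.detect_donor(
            small_lawn.channels["did"], None, small_lawn.labels, cfg
        )
        assert donor.is_control
        assert donor.donor_cell_label == pseudo_donor_oracle(
            small_lawn.labels, small_lawn.channels.voxel_size
        )

    def test_two_donors_in_different_cells_rejected(self, small_lawn, cfg):
        labels = small_lawn.labels
        vv = ci.voxel_volume(small_lawn.channels["did"])
        did = small_lawn.channels["did"].intensities.copy()
        # saturate two different cells wholesale (each > 1,000 um^3)
        cells = [l for l in np.unique(labels) if l > 0]
        counts = {l: (labels == l).sum() for l in cells}
        big = [l for l in cells if counts[l] * vv > 1000][:2]
        assert len(big) == 2
        for l in big:
            did[labels == l] = 255
        with pytest.raises(MultipleDonorsError):
            ci.detect_donor(_stack(did), None, labels, cfg)

    def test_egfp_union_extends_donor(self, small_lawn, cfg):
        """EGFP-only donor signal still yields a donor via the channel union."""
        donor_only_did = ci.detect_donor(
            small_lawn.channels["did"], None, small_lawn.labels, cfg
        )
        assert donor_only_did.is_control
        egfp = small_lawn.channels["did"].intensities.copy()
        target = donor_only_did.donor_cell_label
        egfp[small_lawn.labels == target] = 255
        donor = ci.detect_donor(
            small_lawn.channels["did"], _stack(egfp), small_lawn.labels, cfg
        )
        assert not donor.is_control
        assert donor.donor_cell_label == target

    def test_weak_donor_flagged(self, small_lawn, cfg):
        """A donor-sized blob above the transfer threshold but below the donor
        level marks the stack for review instead of being quantified."""
        did = small_lawn.channels["did"].intensities.copy()
        lab = pseudo_donor_oracle(small_lawn.labels, VS)
        did[small_lawn.labels == lab] = 150  # bright but unsaturated
        donor = ci.detect_donor(_stack(did), None, small_lawn.labels, cfg)
        assert donor.is_control and donor.weak_donor


class TestSelectPseudoDonor:
    def test_single_cell(self):
        labels = np.zeros((4, 8, 8), np.int32)
        labels[1:3, 2:6, 2:6] = 1
        assert ci.select_pseudo_donor(labels, (1, 1, 1)) == 1

    def test_symmetric_tie_takes_lower_label(self):
        labels = np.zeros((1, 4, 9), np.int32)
        labels[0, 1:3, 1:4] = 2
        labels[0, 1:3, 5:8] = 1
        # both centroids 2 px from the centre column -> lower label wins
        assert ci.select_pseudo_donor(labels, (1, 1, 1)) == 1

    def test_matches_exhaustive_search(self, small_lawn):
        got = ci.select_pseudo_donor(small_lawn.labels, VS)
        assert got == pseudo_donor_oracle(small_lawn.labels, VS)

    def test_empty_map_is_error(self):
        with pytest.raises(CodeitError):
            ci.select_pseudo_donor(np.zeros((2, 2, 2), np.int32), (1, 1, 1))


class TestQuantifyTransfer:
    def test_at_threshold_counts_nothing(self, small_lawn, cfg):
        """'Above threshold' is strict: intensity == threshold is excluded."""
        flat = np.full(small_lawn.labels.shape, cfg.did_threshold, np.uint8)
        donor = ci.detect_donor(small_lawn.channels["did"], None, small_lawn.labels, cfg)
        res = ci.quantify_transfer(
            _stack(flat), small_lawn.labels, donor, cfg.did_threshold, cfg
        )
        assert res.total_transfer_voxels == 0
        assert res.total_transfer_intensity == 0

    def test_ground_truth_recovered_exactly(self, painted, small_lawn, cfg):
        channels, gt, _ = painted
        donor = ci.detect_donor(channels["did"], None, small_lawn.labels, cfg)
        res = ci.quantify_transfer(
            channels["did"], small_lawn.labels, donor, cfg.did_threshold, cfg
        )
        recs = records_by_label(res)
        for lab, rec in recs.items():
            if rec.excluded:
                continue
            assert rec.transfer_intensity == gt.transfer_intensity[lab]
            assert rec.transfer_voxels == gt.transfer_voxels[lab]
        # totals conservation
        inc = res.included_records()
        assert res.total_transfer_voxels == sum(r.transfer_voxels for r in inc)
        assert res.total_transfer_intensity == sum(r.transfer_intensity for r in inc)

    def test_matches_triple_loop_oracle(self, painted, small_lawn, cfg):
        channels, _, _ = painted
        donor = ci.detect_donor(channels["did"], None, small_lawn.labels, cfg)
        res = ci.quantify_transfer(
            channels["did"], small_lawn.labels, donor, cfg.did_threshold, cfg
        )
        counts, sums = per_cell_transfer_oracle(
            channels["did"].intensities, small_lawn.labels,
            donor.dilated_mask, cfg.did_threshold,
        )
        for rec in res.records:
            assert rec.transfer_voxels == counts[rec.cell_label]
            assert rec.transfer_intensity == sums[rec.cell_label]

    def test_small_cell_excluded(self, cfg):
        labels = np.zeros((6, 20, 20), np.int32)
        labels[1:5, 2:12, 2:12] = 1  # 400 voxels ~ 80 um^3 at default voxel
        labels[1:5, 13:19, 2:12] = 2
        vv = 1.01 * 0.445 * 0.445
        assert 400 * vv < cfg.cell_min_volume
        did = np.zeros(labels.shape, np.uint8)
        did[2, 5, 5] = 200  # punctum inside the small cell
        donor = ci.DonorDefinition(
            mask=np.zeros_like(labels, bool),
            dilated_mask=np.zeros_like(labels, bool),
            donor_cell_label=2,
            is_control=True,
        )
        res = ci.quantify_transfer(_stack(did), labels, donor, cfg.did_threshold, cfg)
        rec = records_by_label(res)[1]
        assert rec.excluded and rec.exclusion_reason == "small_volume"
        assert res.total_transfer_intensity == 0

    def test_lateral_boundary_cell_excluded_z_not(self, small_lawn, cfg, painted):
        channels, gt, _ = painted
        labels = small_lawn.labels
        donor = ci.detect_donor(channels["did"], None, labels, cfg)
        res = ci.quantify_transfer(channels["did"], labels, donor, cfg.did_threshold, cfg)
        lateral = set()
        for face in (labels[:, 0, :], labels[:, -1, :], labels[:, :, 0], labels[:, :, -1]):
            lateral.update(np.unique(face).tolist())
        for rec in res.records:
            if rec.cell_label in lateral:
                assert rec.excluded and rec.exclusion_reason == "boundary"
            else:
                # every cell touches the z faces' slab limits; that never excludes
                assert rec.exclusion_reason != "boundary"

    def test_donor_rim_blanked(self, small_lawn, cfg):
        """Signal only inside the one-voxel dilated rim contributes nothing."""
        from scipy.ndimage import binary_dilation

        labels = small_lawn.labels
        donor_lab = pseudo_donor_oracle(labels, VS)
        mask = labels == donor_lab
        dilated = binary_dilation(mask, np.ones((3, 3, 3)))
        rim = dilated & ~mask
        did = np.zeros(labels.shape, np.uint8)
        did[rim] = 250
        donor = ci.DonorDefinition(mask, dilated, donor_lab, is_control=False)
        res = ci.quantify_transfer(_stack(did), labels, donor, cfg.did_threshold, cfg)
        assert res.total_transfer_voxels == 0
        assert res.total_transfer_intensity == 0

    def test_threshold_monotonicity(self, painted, small_lawn, cfg):
        channels, _, _ = painted
        donor = ci.detect_donor(channels["did"], None, small_lawn.labels, cfg)
        prev_vox, prev_int = None, None
        for thr in (80, 120, 180, 240):
            res = ci.quantify_transfer(channels["did"], small_lawn.labels, donor, thr, cfg)
            if prev_vox is not None:
                assert res.total_transfer_voxels <= prev_vox
                assert res.total_transfer_intensity <= prev_int
            prev_vox, prev_int = res.total_transfer_voxels, res.total_transfer_intensity

    def test_unspecific_signal_reported_not_counted(self, small_lawn, cfg):
        labels = small_lawn.labels
        did = np.zeros(labels.shape, np.uint8)
        did[labels == 0] = 200  # all signal outside cells
        donor = ci.DonorDefinition(
            np.zeros_like(labels, bool), np.zeros_like(labels, bool),
            donor_cell_label=1, is_control=True,
        )
        res = ci.quantify_transfer(_stack(did), labels, donor, cfg.did_threshold, cfg)
        assert res.total_transfer_intensity == 0
        assert res.unspecific_intensity == 200 * int((labels == 0).sum())


class TestSignalDensity:
    def test_uniform_voxels(self):
        res = ci.StackResult("s", False, 1, (), 10, 2000, 0)
        assert ci.signal_density(res) == 200.0

    def test_zero_voxels_is_missing(self):
        res = ci.StackResult("s", True, 1, (), 0, 0, 0)
        assert ci.signal_density(res) is None

    def test_matches_oracle_ratio(self, painted, small_lawn, cfg):
        channels, _, _ = painted
        donor = ci.detect_donor(channels["did"], None, small_lawn.labels, cfg)
        res = ci.quantify_transfer(
            channels["did"], small_lawn.labels, donor, cfg.did_threshold, cfg
        )
        counts, sums = per_cell_transfer_oracle(
            channels["did"].intensities, small_lawn.labels,
            donor.dilated_mask, cfg.did_threshold,
        )
        included = [r.cell_label for r in res.included_records()]
        assert ci.signal_density(res) == pytest.approx(
            sums[included].sum() / counts[included].sum()
        )


class TestExportResults:
    def _results(self, painted, small_lawn, cfg):
        channels, _, _ = painted
        donor = ci.detect_donor(channels["did"], None, small_lawn.labels, cfg)
        r1 = ci.quantify_transfer(
            channels["did"], small_lawn.labels, donor, cfg.did_threshold, cfg, "stack_b"
        )
        ctrl_lawn = ci.generate_control_stack(
            ci.LawnSpec(shape=(12, 64, 64), n_cells=6, slab_z=(2, 10), seed=21)
        )
        donor_c = ci.detect_donor(ctrl_lawn.channels["did"], None, ctrl_lawn.labels, cfg)
        r2 = ci.quantify_transfer(
            ctrl_lawn.channels["did"], ctrl_lawn.labels, donor_c,
            cfg.did_threshold, cfg, "stack_a",
        )
        return [r1, r2]

    def test_row_count_and_round_trip(self, painted, small_lawn, cfg, tmp_path):
        results = self._results(painted, small_lawn, cfg)
        p = tmp_path / "results.tsv"
        ci.export_results(results, p)
        df = ci.read_results(p)
        n_cells = sum(len(r.records) for r in results)
        assert len(df) == n_cells + len(results)  # + one totals row per stack
        for res in results:
            sub = df[(df.stack_id == res.stack_id) & (df.row_type == "totals")]
            assert int(sub.transfer_intensity.iloc[0]) == res.total_transfer_intensity
            assert int(sub.transfer_voxels.iloc[0]) == res.total_transfer_voxels
            for rec in res.records:
                row = df[
                    (df.stack_id == res.stack_id) & (df.cell_label == rec.cell_label)
                ].iloc[0]
                assert int(row.transfer_intensity) == rec.transfer_intensity
                assert bool(row.excluded) == rec.excluded

    def test_control_flag_and_stable_order(self, painted, small_lawn, cfg, tmp_path):
        results = self._results(painted, small_lawn, cfg)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        ci.export_results(results, p1)
        ci.export_results(list(reversed(results)), p2)
        assert p1.read_text() == p2.read_text()  # ordering is canonical
        df = ci.read_results(p1)
        assert df[df.stack_id == "stack_a"].is_control.all()
        assert not df[df.stack_id == "stack_b"].is_control.any()

    def test_empty_export_is_error(self, tmp_path):
        with pytest.raises(CodeitError):
            ci.export_results([], tmp_path / "x.tsv")
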