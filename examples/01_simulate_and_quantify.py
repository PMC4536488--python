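"""Generate a synthetic co-culture stack and quantify intercellular transfer.

Builds a confluent acceptor lawn with one half-saturated donor cell and
punctate DiD transfer of known intensity, runs donor detection and per-cell
quantification, and compares the measurement with the painted ground truth.
"""

import codeit as ci

lawn = ci.generate_lawn(ci.LawnSpec(seed=42))
tspec = ci.random_transfer_spec(lawn, seed=43)
channels, truth = ci.paint_donor_and_transfer(lawn, tspec)

cfg = ci.QuantConfig()
donor = ci.detect_donor(channels["did"], None, lawn.labels, cfg)
result = ci.quantify_transfer(
    channels["did"], lawn.labels, donor, cfg.did_threshold, cfg, stack_id="demo"
)

print(f"donor cell: detected label {donor.donor_cell_label}, "
      f"ground truth {truth.donor_label}")
print(f"stack totals: {result.total_transfer_intensity} grayscale units over "
      f"{result.total_transfer_voxels} voxels "
      f"(density {ci.signal_density(result):.1f}/voxel)")
print("per-cell transfer (acceptors with painted signal):")
for rec in result.included_records():
    if rec.transfer_voxels == 0:
        continue
    painted = truth.transfer_intensity[rec.cell_label]
    print(f"  cell {rec.cell_label:3d}: measured {rec.transfer_intensity:6d} "
          f"(painted {painted:6d}) in {rec.transfer_voxels} voxels "
          f"-> {'exact' if rec.transfer_intensity == painted else 'MISMATCH'}")
# Totals count only included acceptor cells: the donor itself is blanked and
# boundary-touching or sub-100-um^3 cells are excluded.
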