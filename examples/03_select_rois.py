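"""Select acquisition positions on a synthetic whole-well mosaic.

Renders a 2x2-tile low-resolution well scan with several donors and a
confluent nucleus field, assembles the super-image, and picks qualified
donor positions (isolated by >= 200 um, >= 15 nuclei within 200 um) plus
random donor-free control positions.
"""

import numpy as np

import codeit as ci

spec = ci.random_well_spec(seed=11, n_donors=6)
mosaic = ci.generate_well_mosaic(spec)
si = ci.assemble_superimage(mosaic.tiles, mosaic.um_per_px)

cfg = ci.QuantConfig()
donors = ci.find_donors_2d(si, cfg)
donor_rois, control_rois = ci.select_rois(si, cfg, seed=1)

print(f"well extent: {si.extent_um[0]:.0f} x {si.extent_um[1]:.0f} um, "
      f"{len(mosaic.nucleus_positions)} nuclei, "
      f"{len(mosaic.donor_positions)} donors placed")
print(f"donors detected: {len(donors)}, qualified for imaging: {len(donor_rois)}")
for r in donor_rois:
    print(f"  donor at ({r.center_um[0]:7.1f}, {r.center_um[1]:7.1f}) um: "
          f"nearest other donor {r.nearest_donor_distance:.0f} um, "
          f"{r.nuclei_in_radius} nuclei in radius")
print(f"control positions accepted: {len(control_rois)} (max {cfg.max_controls})")
# Disqualified donors sit within 200 um of another donor; each control is
# donor-free, dense enough, and its field overlaps no other selected field.
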