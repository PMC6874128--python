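#!/usr/bin/env python
"""Render the synthetic two-timepoint case and tabulate its ground truth.

The case carries one primary tumor (necrotic core, low-BV and low-ADC
blobs, -16.2% volume at fraction 10, ADC rising from 1.34 to 1.62 um^2/ms)
and one clean nodal tumor. Writes the ground-truth subvolume volumes and
the rendered NIfTI volumes under results/.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from hnqi.io import RunConfig, write_mask, write_volume
from hnqi.phantom import render_phantom
from hnqi.pipeline import default_case_spec
from hnqi.subvolumes import Thresholds, extract_subvolumes

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

spec = default_case_spec(RunConfig(seed=args.seed))
case = render_phantom(spec)

rows = []
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for tp in ("pre", "mid"):
        data = case.timepoint(tp)
        for i, tm in enumerate(spec.tumors):
            sv = extract_subvolumes(data.truth, data.gtv_masks[i], Thresholds())
            rows.append({"tumor": f"T{i}", "kind": tm.kind, "timepoint": tp, **sv.volumes_cc})

df = pd.DataFrame(rows)
args.out.mkdir(parents=True, exist_ok=True)
df.to_csv(args.out / "phantom_truth_volumes.csv", index=False)

vol_dir = args.out / "phantom_volumes"
vol_dir.mkdir(exist_ok=True)
for tp in ("pre", "mid"):
    data = case.timepoint(tp)
    for b, grid in data.dwi.items():
        write_volume(grid, vol_dir / f"dwi_b{int(b)}_{tp}.nii.gz")
    write_volume(data.suv, vol_dir / f"suv_{tp}.nii.gz")
    for i, m in enumerate(data.gtv_masks):
        write_mask(m, vol_dir / f"gtv_T{i}_{tp}.nii.gz")

print(df.to_string(index=False))
pre_gtv = df.query("tumor=='T0' and timepoint=='pre'")["gtv_cc"].iloc[0]
mid_gtv = df.query("tumor=='T0' and timepoint=='mid'")["gtv_cc"].iloc[0]
print(f"\nprimary GTV change at fraction 10: {(mid_gtv - pre_gtv) / pre_gtv:+.1%} "
      f"(generator target -16.2%)")
print(f"tables -> {args.out}/phantom_truth_volumes.csv, volumes -> {vol_dir}/")
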