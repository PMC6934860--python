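"""Generate one synthetic cohort of raw inputs and write them to disk.

Produces, under results/inputs/: a calcein time-lapse stack + ground
truth masks per cell line, a DCFDA (ROS) stack per line, MTS plates
for three drugs in both culture modes, and four-tube flow-cytometry
event tables.  These files exercise the same I/O paths a real
Incucyte/plate-reader/FACS export would use.

Run:  python analysis/01_simulate_inputs.py [--seed 1]
"""

import argparse
from pathlib import Path

from mcsmdr.containers import write_masks, write_stack
from mcsmdr.synthetic import (
    PHENOTYPES,
    SpheroidGeometry,
    flow_spec_for,
    make_flow_events,
    make_plate,
    make_ros_stack,
    make_spheroid_stack,
    plate_spec_for,
)

LINES = {"MCS_17": "sensitive", "MCS_02": "moderate", "MCS_08": "resistant"}


def main(seed: int, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    geo = SpheroidGeometry(center=(64, 64), radius=40.0)
    for i, (label, pheno_name) in enumerate(LINES.items()):
        pheno = PHENOTYPES[pheno_name]
        stack, masks = make_spheroid_stack(pheno, geo, seed=seed + i,
                                           image_size=128)
        write_stack(out / f"{label}_calcein.tif", stack)
        write_masks(out / f"{label}_calcein_truth.tif", masks)
        ros, _ = make_ros_stack(pheno, geo, duration_h=1.0, seed=seed + i,
                                image_size=128)
        write_stack(out / f"{label}_ros.tif", ros)
        for drug in ("doxorubicin", "cisplatin", "methotrexate"):
            for mode in ("2D", "MCS"):
                spec = plate_spec_for(pheno_name, drug, mode, noise_sd=0.03)
                make_plate(spec, seed=seed + i, mode=mode).to_csv(
                    out / f"{label}_{drug}_{mode}_plate.csv", index=False)
        make_flow_events(flow_spec_for(pheno_name), seed=seed + i).to_csv(
            out / f"{label}_flow.csv", index=False)
        print(f"{label} ({pheno_name}): stack {stack.n_frames} frames, "
              f"6 plates, flow events written")
    print(f"inputs -> {out}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/inputs"))
    args = ap.parse_args()
    main(args.seed, args.out)
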