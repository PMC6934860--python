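"""End-to-end resistance profiling: the pipeline's integrated endpoint.

Runs the full simulation-backed pipeline (segment -> quantify ->
IC50 -> flow -> classify) for the three-line cohort over several
seeds and reports the 3-class recovery rate and the confusion
structure.  Also reproduces the qualitative published pattern:
a cohort whose uptake, IC50 ranks, ROS and inhibitor responses follow
the printed orderings must classify as sensitive / moderately
resistant / highly resistant.

Writes results/profile_recovery.json and per-seed reports under
results/profiles/.

Run:  python analysis/06_profile_resistance.py [--seed 1 --n-seeds 5]
"""

import argparse
import json
from pathlib import Path

from mcsmdr.profile import PipelineConfig, run_pipeline

EXPECTED = {"MCS_17": "sensitive", "MCS_02": "moderately_resistant",
            "MCS_08": "highly_resistant"}


def main(seed: int, n_seeds: int, segmentation: str, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    model = None
    if segmentation == "pnet":
        from mcsmdr.segmentation import load_model

        ckpt = out / "pnet_128.npz"
        if not ckpt.exists():
            raise SystemExit("train the segmenter first: "
                             "python analysis/02_train_segmenter.py")
        model = load_model(ckpt)
    correct, total, confusions = 0, 0, []
    for s in range(n_seeds):
        cfg = PipelineConfig(seed=seed + s, segmentation=segmentation,
                             pnet_model=model)
        rep = run_pipeline(cfg, out_dir=out / "profiles" / f"seed_{seed + s}")
        for label, sub in rep["subjects"].items():
            got = sub["profile"]["class"]
            total += 1
            if got == EXPECTED[label]:
                correct += 1
            else:
                confusions.append((label, EXPECTED[label], got))
    summary = {"n_seeds": n_seeds, "segmentation": segmentation,
               "recovery_rate": correct / total, "confusions": confusions}
    (out / "profile_recovery.json").write_text(json.dumps(summary, indent=2))
    print(f"{correct}/{total} correct classes over {n_seeds} seeds "
          f"({segmentation} masks)")
    for c in confusions:
        print("  confusion:", c)


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-seeds", type=int, default=5)
    ap.add_argument("--segmentation", default="baseline",
                    choices=["ground_truth", "baseline", "pnet"])
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    main(args.seed, args.n_seeds, args.segmentation, args.out)
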