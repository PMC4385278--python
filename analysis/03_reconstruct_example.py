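#!/usr/bin/env python
"""Reconstruct one noisy acquisition with OSEM and post-filter it.

Takes the first LEHR/125 MBq noise realisation of the mini-scale healthy
and COPD phantoms, runs OSEM (16 subsets, 4 iterations = 64 updates) with
attenuation and collimator-response compensation, applies the 0.6 cycles/cm
Butterworth filter, and writes the volumes as NIfTI.  Prints the global
count-consistency QC metric (reprojected vs measured counts).

Usage: python analysis/03_reconstruct_example.py [--seed 1] [--iterations 4]
"""

import argparse
from pathlib import Path

from cvtspect import (Experiment, FilterSpec, OsemReconstructor, ReconConfig,
                      apply_filter, count_consistency, mini_scale)
from cvtspect.io import save_image


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--iterations", type=int, default=4)
    ap.add_argument("--cutoff", type=float, default=0.6)
    ap.add_argument("--out", type=Path, default=Path("results/recon"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ex = Experiment(mini_scale(base_seed=args.seed))
    cfg = ReconConfig(n_subsets=16, n_iterations=args.iterations)
    recon = OsemReconstructor(ex.phantom()["mu"], ex.config.geometry, "LEHR", cfg,
                              system=ex.system("LEHR"))
    for diseased, label in [(False, "healthy"), (True, "copd")]:
        noisy = ex.realisations("LEHR", 125, diseased)[0]
        image = recon.reconstruct(noisy)
        mismatch = count_consistency(image, noisy, ex.system("LEHR"))
        filtered = apply_filter(image, FilterSpec(args.cutoff))
        save_image(args.out / f"{label}_osem{cfg.n_updates}.nii.gz", image)
        save_image(args.out / f"{label}_osem{cfg.n_updates}_q{args.cutoff:g}.nii.gz", filtered)
        print(f"{label}: {cfg.n_updates} updates, count consistency = {mismatch:.4f}")
    print(f"reconstructions written to {args.out}/")


if __name__ == "__main__":
    main()
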