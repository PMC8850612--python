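#!/usr/bin/env python
"""Inter-subject noise ceiling of the demo subjects.

For each subject, the shared-response-model ceiling: ridge from the
averaged responses of the other five subjects to the target subject's
responses, same blocked CV and scoring as the encoding models. The
ceiling bounds how much of each subject's signal any stimulus-driven
model could explain at this SNR. Writes results/demo/ceiling.tsv.
"""

import numpy as np
from importlib import import_module

sim = import_module("01_simulate")


def main() -> None:
    cfg = sim.CONFIG
    cfg = type(cfg)(**{**cfg.to_dict(), "stages": ("simulate", "ceiling")})
    art = sim.run(cfg, sim.OUT)
    resp = art["brain_truth"].responsive_mask
    for subj, cmap in art["ceilings"].items():
        print(f"subject {subj}: ceiling R = "
              f"{cmap.scores[resp].mean():+.3f} (responsive voxels), "
              f"{cmap.scores[~resp].mean():+.3f} (silent voxels)")
    all_r = np.stack([c.scores[resp] for c in art["ceilings"].values()])
    print(f"group ceiling: {all_r.mean():+.3f} ± "
          f"{all_r.mean(axis=1).std(ddof=1) / np.sqrt(all_r.shape[0]):.3f}")


if __name__ == "__main__":
    main()
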