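#!/usr/bin/env python
"""Brain scores for every embedding of the demo study.

Runs the blocked-CV ridge pipeline (z-scored features, FIR expansion,
per-target LOO λ, Pearson scoring on held-out scans) for each embedding ×
subject and prints the average score of the three canonical levels —
visual, lexical (word embedding), compositional — which should be ordered
visual < lexical < compositional because the responses were generated
from the compositional level.
"""

import numpy as np

from neuroscore.comparison import average_scores

from importlib import import_module

sim = import_module("01_simulate")


def main() -> None:
    cfg = sim.CONFIG
    cfg = type(cfg)(**{**cfg.to_dict(), "stages": ("simulate", "extract",
                                                   "score")})
    art = sim.run(cfg, sim.OUT)
    maps = art["score_maps"]
    levels = art["levels"]
    recs = art["recordings"]
    for name in ("visual", "lexical", "compositional"):
        key = levels[name].card.key()
        per_subj = [average_scores(maps[(key, r.subject_id)]) for r in recs]
        print(f"{name:>14}: R = {np.mean(per_subj):+.3f} "
              f"± {np.std(per_subj, ddof=1) / np.sqrt(len(per_subj)):.3f} "
              f"(mean ± SEM, n={len(per_subj)})")


if __name__ == "__main__":
    main()
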