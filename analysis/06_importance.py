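#!/usr/bin/env python
"""Permutation feature importance of model properties on the demo family.

Fits, per subject, a random forest from the seven model properties to
the average brain score and reports the permutation importance ΔR of
each property with adjacent-pair Wilcoxon comparisons. In the demo the
planted driver is the checkpoint's accuracy, so accuracy (and its
correlate, training step) should dominate. Writes
results/demo/importance.tsv.
"""

from importlib import import_module

sim = import_module("01_simulate")


def main() -> None:
    cfg = sim.CONFIG
    cfg = type(cfg)(**{**cfg.to_dict(),
                       "stages": ("simulate", "score", "compare",
                                  "importance")})
    art = sim.run(cfg, sim.OUT)
    print(art["ranking"].to_string(index=False,
                                   float_format=lambda x: f"{x:+.4f}"))
    pairs = art["importance_pairs"]
    print("\nadjacent-pair Wilcoxon p-values:")
    for _, row in pairs.iterrows():
        print(f"  {row['top']} > {row['runner_up']}: p = {row['p']:.3f}")


if __name__ == "__main__":
    main()
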