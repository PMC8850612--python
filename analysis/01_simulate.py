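#!/usr/bin/env python
"""Generate the demo dataset: stimuli, embedding family, brain responses.

Writes stimuli.tsv and arrays.h5 (embeddings + 6 subjects' fMRI) under
results/demo/ and prints the dataset's shape. All later analysis scripts
re-derive their inputs from the same config and seed, so the whole demo
is reproducible bit-identically.
"""

from pathlib import Path

from neuroscore.pipeline import RunConfig, run

OUT = Path(__file__).resolve().parents[1] / "results" / "demo"

# 12 subjects: enough for the exact Wilcoxon's minimal two-sided p
# (2/2^12) to survive BH correction across the 40 voxels
CONFIG = RunConfig(seed=1, n_sentences=30, n_subjects=12, n_channels=40,
                   dim=12, n_layers=3, n_steps=6, snr=1.0,
                   stages=("simulate",))


def main() -> None:
    art = run(CONFIG, OUT)
    st = art["stimuli"]
    print(f"stimuli: {len(st)} words, {len(st.sentences())} sentences, "
          f"{len(st.blocks())} blocks, run ends at {st.end_time():.1f} s")
    print(f"embedding family: {len(art['family'])} checkpoints×layers, "
          f"dim {CONFIG.dim}")
    print(f"recordings: {len(art['recordings'])} subjects × "
          f"{art['recordings'][0].data.shape} (scans × voxels)")
    print(f"artifacts in {OUT}")


if __name__ == "__main__":
    main()
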