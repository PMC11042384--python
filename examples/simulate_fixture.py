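"""Generate a complete synthetic CRISPRi screen as TSV files.

Writes a guide library over DHSs, annotation features with missingness,
ground truth, and per-task outcome tables (fitness counts/log2FC/adj_p,
wild-type abundance, gRNA-gene expression pairs), then summarizes the
derived labels.
"""

import sys
from pathlib import Path

from guidescreen import derive_labels
from guidescreen.simulate import SimConfig, write_fixture_dir

out_dir = Path(sys.argv[1]) if len(sys.argv) > 1 else Path("scratch/fixture")
config = SimConfig(n_dhs=100, guides_per_dhs=8, seed=7)
data = write_fixture_dir(out_dir, config)

print(f"wrote {len(list(out_dir.iterdir()))} files to {out_dir}/:")
for p in sorted(out_dir.iterdir()):
    print(f"  {p.name}")

labeled = derive_labels(data["fitness"])
print("\nfitness label counts (adj_p < 0.05 significant, > 0.2 insignificant,")
print("gray zone excluded from training):")
print(labeled["label"].value_counts().to_string())
print(f"\ntrue-effect fraction planted by the simulator: "
      f"{data['truth']['true_effect'].mean():.3f}")
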