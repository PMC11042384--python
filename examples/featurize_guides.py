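"""Encode protospacers as one-hot matrices and bag-of-words vectors.

Builds a three-guide library, produces both sequence representations and
prints the block-sum invariants of the 404-feature BoW encoding.
"""

import pandas as pd

from guidescreen import bow_feature_names, featurize_library, one_hot_decode

library = pd.DataFrame({
    "guide_id": ["g1", "g2", "g3"],
    "protospacer": ["ACGTACGTACGTACGTACGT", "GGGGCCCCAAAATTTTACGT", "A" * 20],
})

one_hot, bow = featurize_library(library)

print(f"one-hot tensor shape: {one_hot.shape}  (guides x bases x positions)")
print(f"decoded g2: {one_hot_decode(one_hot[1])}")
print(f"BoW matrix shape: {bow.shape}  ({len(bow_feature_names())} features)")

# block sums: 20 positional mononucleotides, 19 positional dinucleotides,
# 20 mononucleotide counts, 19 dinucleotide counts -- for every guide
blocks = {
    "positional mono (should be 20)": bow.iloc[:, :80].sum(axis=1),
    "positional di   (should be 19)": bow.iloc[:, 80:384].sum(axis=1),
    "freq mono       (should be 20)": bow.iloc[:, 384:388].sum(axis=1),
    "freq di         (should be 19)": bow.iloc[:, 388:].sum(axis=1),
}
for name, sums in blocks.items():
    print(f"{name}: {sums.tolist()}")
print("Non-zero features of the homopolymer g3:")
nz = bow.loc["g3"]
print(nz[nz > 0].to_string())
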