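"""Generate a motif-planted peptide dataset and encode it four ways.

Positives carry the SUMOylation consensus motif ΨKX[ED] or the inverted
motif [ED]XKΨ around the central lysine; negatives are background-only.
"""

from sumosite import (
    MotifModel,
    SyntheticDatasetSpec,
    encode_windows,
    generate_peptides,
    load_aaindex_table,
)

spec = SyntheticDatasetSpec(
    n_pos=500, n_neg=500,
    motif=MotifModel(p_consensus=0.5, p_inverted=0.5, L=39, seed=42),
)
ds = generate_peptides(spec)
print(f"{len(ds)} windows, {int(ds.labels.sum())} positive")
print("example positive window:", ds.windows[0].sequence)

table = load_aaindex_table()
table14 = table.with_selection(table.selected_ids[:14])
for scheme, kwargs in [
    ("eaac", {}), ("blosum62", {}),
    ("aaindex", {"aaindex_table": table14}), ("zscale", {}),
]:
    X = encode_windows(ds.sequences, scheme, **kwargs)
    flat = X.shape[1] * X.shape[2]
    print(f"{scheme:9s}: {X.shape[1]:2d} x {X.shape[2]:2d} matrix "
          f"-> {flat} features per window")
# The four flattened sizes (700, 780, 546, 195 for a 39-mer) are the feature
# vectors the tree baselines consume; the networks keep the 2-D layout.
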