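"""Mirror comparison of a predicted and an observed spectrum.

Simulates a TMT-labeled peptide's empirical spectrum, predicts it with a
TMT-flavored model, and exports the aligned fragment table (plus an SVG mirror
plot: prediction up, observation down). A per-spectrum PCC near 1 means the
predicted intensity pattern matches the empirical one.
"""

import peakboost as pb
from peakboost.evaluation import plot_mirror

rules = pb.DEFAULT_RULES["TMT"]
train_pairs, _ = pb.generate_dataset(rules, 300, seed=5)
model = pb.train_model(train_pairs, "TMT", pb.TrainingConfig(n_rounds=150, seed=5))

peptide = pb.Peptide(
    "EENGVLVLNDANFDNFVADK", ((0, "TMT6plex"), (20, "TMT6plex")), charge=2
)
spectrum = pb.simulate_spectrum(rules, peptide, seed=42, identifier="demo")

table = pb.mirror_pair_export(model, peptide, spectrum)
print(table.round(3).to_string(index=False))

tb, ty = pb.extract_targets(peptide, spectrum)
pred = pb.predict_peptide(model, peptide)
pcc = pb.spectrum_pcc((pred.b, pred.y), (tb.values, ty.values))
print(f"\nper-spectrum PCC (predicted vs observed log2 targets): {pcc:.3f}")

plot_mirror(table, "mirror_plot.svg", title=f"{peptide.sequence} (2x TMT), PCC={pcc:.2f}")
print("wrote mirror_plot.svg")
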