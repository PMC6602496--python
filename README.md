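# peakboost

Gradient-boosted prediction of MS² fragment-ion peak intensities for peptides.

## The problem

In shotgun proteomics, peptides are identified from their fragmentation (MS²)
spectra. The *m/z* of each b- and y-ion is trivial to compute from the
sequence, but the *intensities* of those peaks follow complex patterns that
depend on the residues around each cleavage site, the precursor charge, the
instrument and fragmentation method, and chemical labels such as TMT and
iTRAQ. Accurate intensity prediction enables in-silico spectral libraries,
transition selection for targeted proteomics, and rescoring of search-engine
identifications.

peakboost is a library (plus a thin CLI) for people who build or evaluate such
predictors: it trains one pair of gradient-boosted tree regressors (b series,
y series) per instrument/label **flavor** — CID, HCD, TripleTOF 5600+, TMT,
iTRAQ, and iTRAQ phospho — and evaluates predictions against empirical spectra.

## The model

For a peptide of length *n* with precursor charge *z*, each cleavage site
*i* ∈ {1, …, n−1} is encoded as a fixed feature vector **x**ᵢ (site position,
charge one-hot, residue composition, physicochemical aggregates of the prefix
and suffix, local residue properties, modification masses). The observed
target is

> tᵢ = log₂ max(Iᵢ / TIC, ε)

where Iᵢ is the intensity of the peak matched to the fragment within a mass
tolerance, TIC is the total ion current of the spectrum, and ε = 0.001 floors
unobserved fragments. Two boosted-tree regressors f_b, f_y are fit with a
squared-error objective so that f_s(**x**ᵢ) ≈ tᵢ for each series s ∈ {b, y}.
Label flavors (TMT, iTRAQ) automatically fix their label modification at the
N-terminus and every lysine. Prediction quality on a spectrum is the Pearson
correlation coefficient (PCC) between the concatenated predicted and observed
[b; y] target vectors.

A seeded synthetic-data generator with a known parametric ground truth stands
in for the large public spectral libraries real models are trained on, so the
entire pipeline — file formats, annotation, training, evaluation — is testable
offline.

## Worked example

```python
import peakboost as pb

# synthetic HCD-style training library (300 peptides) with known ground truth
pairs, _ = pb.generate_dataset(pb.DEFAULT_RULES["HCD"], 300, seed=1)
model = pb.train_model(pairs, "HCD", pb.TrainingConfig(n_rounds=150, seed=1))

pred = pb.predict_peptide(model, pb.Peptide("ACDEFGHIKLNPQR", charge=2))
peaks = pred.to_peaks()
```

Running `python examples/predict_intensities.py` (which is exactly this)
prints:

```
predicted fragment intensities for ACDEFGHIKLNPQR/2:
  ion        m/z intensity
b1       72.0444     0.014
b2      175.0536     0.015
b3      290.0805     0.028
b4      419.1231     0.059
...
```

Each row is a fragment ion with its theoretical m/z and predicted relative
intensity (base peak = 1). `examples/cross_model_matrix.py` trains three
flavor models and prints the matched-vs-mismatched median-PCC matrix:

```
                HCD    TMT  iTRAQphospho
HCD           0.854 -0.382         0.373
TMT          -0.386  0.874        -0.231
iTRAQphospho  0.426 -0.249         0.888

matched mean = 0.872, mismatched mean = -0.075.
```

The dominant diagonal is the specialization effect: a model only predicts
well on data from its own instrument/label context. See also
`examples/mirror_plot.py` (predicted-vs-observed mirror spectrum) and
`examples/simulate_and_roundtrip.py` (format round-trips).

## Command line

```sh
peakboost simulate --flavor HCD --n 500 --seed 1 --out lib      # synthetic MSP
peakboost train --library lib.msp --flavor HCD --out model
peakboost predict --peptides requests.csv --model model --out pred --formats csv,mgf,msp
peakboost evaluate --model model --library eval.msp --out scores
peakboost xeval --model m1 --model m2 --library a.msp --library b.msp --out matrix.csv
peakboost convert --library lib.msp --out lib --to ssl_ms2
```

Peptide request CSVs have columns `spec_id, peptide, modifications, charge`
with modifications such as `0|TMT6plex|20|TMT6plex` (position 0 = N-terminus,
1-based residues). Supported spectrum formats: MGF, NIST-style MSP, and
BiblioSpec/Skyline SSL + MS2.

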