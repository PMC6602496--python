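# Methods

## Scope and model structure

peakboost predicts the intensities of singly charged b- and y-fragment ions
of a peptide's MS² spectrum. Six model flavors are built in, each binding a
fragmentation context and its fixed label chemistry:

| flavor | fragmentation | analyzer | fixed labels | default tolerance |
|---|---|---|---|---|
| CID | CID | linear ion trap | — | 0.5 Da |
| HCD | HCD | Orbitrap | — | 0.02 Da |
| TripleTOF5600 | CID | QTOF | — | 0.02 Da |
| TMT | HCD | Orbitrap | TMT6plex (N-term, K) | 0.02 Da |
| iTRAQ | HCD | Orbitrap | iTRAQ4plex (N-term, K) | 0.02 Da |
| iTRAQphospho | HCD | Orbitrap | iTRAQ4plex (N-term, K) | 0.02 Da |

A trained model is a pair of gradient-boosted tree regressors (xgboost,
squared-error objective), one per ion series, sharing one feature schema.

## Masses and fragments

All arithmetic is monoisotopic; centroided monoisotopic peaks are assumed.
Residue masses come from pyteomics; the proton mass is 1.00727646688 Da.
Modification positions use the convention 0 = N-terminus, 1-based residues,
n+1 = C-terminus. The built-in modification registry carries TMT6plex
(+229.162932), iTRAQ4plex (+144.102063), Phospho (+79.966331),
Carbamidomethyl (+57.021464) and Oxidation (+15.994915), and is extensible
from YAML (delta mass or elemental composition). Leucine and isoleucine share
a mass but remain distinct letters for feature encoding. Peptides containing
B, J, O, U, X or Z are rejected with an error at the chemistry layer; batch
layers catch, log and skip. Fragment enumeration defaults to 1+ ions;
2+ fragments can be enabled for precursors of charge ≥ 3 but do not take part
in target extraction, which is defined on the 1+ ladder so target vectors are
always length n−1 per series.

## Annotation targets

For each theoretical fragment the nearest observed peak within the tolerance
is taken; each observed peak feeds at most one fragment (resolved greedily by
m/z distance, ties toward the b series and lower index). Matched intensities
are divided by the total ion current over **all** observed peaks — not only
matched ones — so targets are comparable across spectra with different match
rates; whether the upstream tools this mirrors normalize over all or only
annotated peaks is not documented, and the all-peaks choice is ours. The
target is log₂ of the normalized intensity floored at ε = 0.001 (≈ −9.966),
bounding the regression range to about 10 log₂ units. The floor is lossy by
construction: ground-truth intensities below ε cannot be recovered from an
annotated spectrum, so round-trip oracles compare in floored target space.

Dataset-level unique-peptide filtering keeps one spectrum per (sequence,
modification set, precursor charge) key; among duplicates the highest-TIC
spectrum wins (first entry on exact ties) — a deterministic rule where only
"unique" is specified by convention.

## Feature encoding (schema `pb-1`)

Per cleavage site: peptide length, site index, relative position; precursor
charge one-hot clamped at 6+; 20 residue-composition counts; for the prefix
and suffix separately, sum/min/max/mean of four residue scales (gas-phase
basicity normalized to [0,1], Kyte–Doolittle hydrophobicity, helix
propensity, isoelectric point); the four scales for residues at site offsets
−1, 0, +1, +2 (zero-padded at the termini); prefix and suffix modification
mass totals; phospho and label mod counts. 81 features total. The encoder
deliberately contains no spectrum-derived feature and no collision-energy
feature — spectral libraries rarely record CE, so models average over it; on
low-CE data this shows up as reduced correlation, a known limitation rather
than a bug. The exact feature list used by earlier tools of this class is not
public in the source we mirror; this schema is our own and is versioned so
archives refuse to load under a different encoder.

## Training

Defaults: 200 boosting rounds, depth 8, learning rate 0.1, early stopping
after 20 stagnant rounds on an internal peptide-disjoint validation slice
(10 % of training pairs), seed 42. No per-flavor tuning is attempted since no
reference hyperparameters exist. Training is single-threaded (`hist` method,
`nthread=1`) so fixed seeds give bit-identical models. Splits are keyed on
(sequence, modifications, charge) so no peptide leaks across partitions.
Model archives are directories: `manifest.json` (flavor, schema version,
config, seed, ε, tree counts, training summary) plus `b.json` / `y.json`
xgboost boosters; they are portable text.

## Evaluation

Per-spectrum score: Pearson r between concatenated [b; y] log₂ vectors,
floored values included. The log₂ space is a documented choice (linear-space
comparison is available by transforming the vectors; the score is invariant
to affine rescaling either way). Spectra with a constant vector on either
side have undefined r; they are excluded from medians and counted rather than
scored 0, to avoid biasing medians with degenerate spectra. Cross-flavor
evaluation shows each model the peptide in its *own* label state (existing
labels stripped, model labels applied) while target extraction uses the
dataset's true peptides — mismatched model/dataset cells are then meaningful
even between label chemistries that would otherwise clash at the same
positions.

## Synthetic data

The generator emulates the *structure* of flavor-dependent fragmentation:
per-series Gaussian profiles over relative fragment length, the proline
effect (boosted y, suppressed b at Xaa–Pro), b1 suppression, a smooth
basicity-dependent factor from the residues flanking the cleavage, a
label-driven shift of low-index b ions, and phospho-containing-fragment
attenuation. Ground truth is normalized to sum 1 over all 2(n−1) fragments.
Spectra add log-normal multiplicative noise (σ = 0.3), fragment dropout
(p = 0.05) and Poisson contaminant peaks (mean 5/spectrum, exponential
intensities) around a nominal TIC of 10⁴. Peptides are tryptic-like:
K/R-terminated, residues from rough proteome background frequencies, lengths
7–22, charges 2–3 (60/40); the phospho flavor forces one phosphorylated
S/T/Y per peptide.

Ground truth is a function of encoder-visible quantities *by design*: the
task is solvable, so a failing model indicts the pipeline, not the data. The
flip side is that passing tests demonstrate correct plumbing and learnability
only — real fragmentation chemistry (mobile-proton physics, neutral losses,
isotope envelopes, CE dependence) is not modeled, and measured PCCs on
synthetic data say nothing about accuracy on real spectra. Three default
flavor parameter sets ship (HCD-, TMT-, iTRAQ-phospho-like), chosen to be
clearly distinct so matched-vs-mismatched comparisons are informative.

## File formats

MGF via pyteomics; NIST-style MSP and BiblioSpec/Skyline SSL + MS2 are
implemented here (no installed library provides them). The MSP `Mods=` token
follows the NIST `k(pos,res,name)` shape with 0-based residue positions,
N-term as `(-1,-,Name)`, C-term as `(n,-,Name)`. SSL has no mod-name column,
so modified sequences carry bracketed mass offsets (`K[+229.162932]`)
resolved back to registry names by nearest delta within 0.01 Da among mods
valid at that site. Predicted spectra are written in linear space rescaled to
base peak = 10 000 (noted in a header comment); MS2 scan numbers run from 1.
Writers always emit ascending m/z; all write→read pairs round-trip text
fields exactly and numerics to better than 1 × 10⁻⁵ relative.

## Numerical and degenerate-input choices

Zero-TIC spectra raise (nothing to normalize); spectra with only contaminant
peaks annotate to all-floor vectors, which are valid but score as undefined
PCC. Prediction outputs are clipped to [log₂ ε, 0]; linear-space output maps
the floor to exactly 0. The request-level peptide length bounds are 3–100;
the mass layer also accepts bare sequence strings below those bounds so
fragment and single-residue arithmetic stays expressible. The batch row cap defaults
to 100 000 (flag-overridable), mirroring common service limits without
constraining local use.

## Problem sizes used in tests and the acceptance script

Chosen once as desk-scale study conditions: noise-free learnability uses
500 training / 100 held-out peptides (seed 1); the specialization matrix uses
3 flavors × 3 seeds with 300 training / 120 evaluation peptides and 150
boosting rounds; the batch run predicts 10 000 peptides (tests) / 2 000
(acceptance script). Real deployments of this model class train on 10⁵–10⁶
unique peptide spectra; the architecture supports that scale, but nothing at
desk scale should be read as a statement about accuracy achievable on real
libraries.
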