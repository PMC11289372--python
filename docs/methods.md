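# Methods

## The sequencing model

`massnovo` casts de novo peptide sequencing as sequence-to-sequence
translation from a bag of spectrum peaks to a peptide string. Each peak
(m/z, intensity) becomes a d-dimensional embedding: the m/z value through a
fixed bank of sine/cosine waveforms with wavelengths geometrically spaced
between λ_min = 0.001 and λ_max = 10,000 m/z (endpoints included; feature i
of the sine block divides by (λ_min/2π)(λ_max/λ_min)^{i/(d_sin−1)}, the
cosine block analogously), the intensity through a learned linear map, and
the two summed. High-frequency features resolve isotope-scale structure;
low-frequency features encode coarse position; the phase structure lets
attention compare m/z *differences*, which is where residue identity lives.

A transformer encoder (self-attention only, no positional encoding — a
spectrum is an unordered set, and the encoding is permutation-equivariant
by construction) contextualizes the peaks. A transformer decoder predicts
the peptide from C-terminus to N-terminus: its first input position is a
precursor embedding (sinusoidal encoding of the neutral precursor mass plus
a learned vector per charge state 1–10, higher charges clamped to 10), and
subsequent positions are learned token embeddings summed with a sinusoidal
positional encoding that reuses the same waveform machinery over integer
indices. Output scores over the 28-token vocabulary are softmax-normalized;
training minimizes cross-entropy against the ground-truth peptide (stop
token included) under teacher forcing.

The reporting order of peptides is N→C; decoding is internally C→N with
reversal at the boundary, so N-terminal modification tokens are only legal
as the final decoded token before stop — the beam search masks everything
except stop after one is emitted.

### Configuration

| parameter | default | notes |
|---|---|---|
| layers | 9 encoder + 9 decoder | |
| d | 512 | embedding size |
| heads | 8 | |
| feed-forward width | 2d = 1024 | chosen so the default model lands at ≈47.3M trainable parameters |
| vocabulary | 28 tokens | 20 canonical residues (C carbamidomethylated), M+15.994915, N+0.984016, Q+0.984016, N-term +42.010565 / +43.005814 / −17.026549 / +25.980265, stop |
| max peptide length | 100 residues | decoding force-terminates there |
| batch size | 32 spectra | |
| peak learning rate | 5e-4 (5e-5 for fine-tuning) | linear warmup (100,000 steps at publication scale; capped at a tenth of short runs) then cosine decay to zero |
| weight decay | 1e-5 | decoupled (AdamW) |
| dropout | 0 | unstated in the lineage this follows; exposed in the config |
| optimizer | AdamW, β=(0.9, 0.98), ε=1e-9 | the optimizer family is a package choice |
| residual layout | post-norm (`norm_first=False`) | pre-norm available; the desk-scale test model uses it because it tolerates the higher learning rates short runs need |

The combined N-terminal carbamylation + NH3-loss token mass (+25.980265)
is the conventional printed value even though the sum of its components is
25.979265; we keep the printed value for compatibility with standard search
tooling. Monoisotopic residue masses follow the standard table to six
decimals; proton 1.007276466 Da, water 18.010565 Da, neutron 1.00335 Da.

The network and its gradients are implemented in numpy (`massnovo.nn`), a
minimal reverse-mode autodiff whose operations are finite-difference
checked in the test suite. Checkpoints are `.npz` archives holding weights,
the full model configuration, and a vocabulary hash.

## Preprocessing

Filters apply in order: keep peaks with 50 ≤ m/z ≤ 2500 (inclusive); drop
peaks within 2 Th of the observed precursor m/z (the exclusion is applied
on the m/z axis, where peaks live; only the window around the observed
precursor is removed, not satellites at other charge states); drop peaks
strictly below 1% of the base peak; keep the 150 most intense (ties at the
boundary go to lower m/z so output is deterministic); replace intensities
with √I/Σ√I. Preprocessing is idempotent — a processed spectrum passes
through unchanged. Spectra with no surviving peaks are flagged and excluded
from prediction rather than raising; spectra with fewer than 20 surviving
peaks are flagged low-quality but still sequenced.

## Decoding and filtering

Beam search keeps k sequences (default 5). At each step the k best tokens
per live beam are proposed and the k best extensions overall survive, ties
broken by lexicographic token order. Beams terminate on stop, when the
running peptide mass (residues + water) comes within the precursor ppm
tolerance of any isotope-corrected precursor mass (offsets {0, 1} by
default, neutron 1.00335 Da), when it exceeds the heaviest allowed target,
or at the maximum length, so decoding always halts. The returned prediction
is the filter-passing completed beam with the highest summed token
log-probability; if none passes, the best non-matching beam is returned and
flagged. The precursor check is computed on neutral masses:
min_q |m_prec − (m_pred + q·neutron)|·10⁶/m_prec < ε, ε = 30 ppm by
default.

Peptide confidence is the mean softmax probability of the predicted
residues; per-residue scores are the mean of the peptide score and the
residue's own probability. Ranked outputs place filter-failing predictions
after all passing ones.

## Evaluation

A predicted residue is matched when its mass differs from the
corresponding ground-truth residue by < 0.1 Da and either the preceding
prefix masses or the following suffix masses agree within 0.5 Da.
Correspondence is a greedy two-pass alignment — forward over prefix masses,
then backward over suffix masses from the first unmatched position — which
makes results reproducible bit for bit. Isobaric confusions (I/L, K/Q at
0.036 Da, deamidated N vs D) therefore count as matches; modified and
unmodified residues compare by mass only. A peptide is correct when all its
tokens match and its length equals the truth. Precision-coverage curves
sort predictions by confidence (filter failures last; ties resolved by
stable sort); average precision is the trapezoidal area under the curve
with the zero-coverage point prepended. The amino-acid-level curve ranks
individual residues by their per-residue scores, with coverage measured
against the total ground-truth residue count. With zero predictions the
AP is reported as null, not 0.

## Grounding

Predictions are matched as substrings (I/L collapsed — they are
indistinguishable by mass) against target proteins and per-protein residue
shuffles generated with the run seed (decoys preserve length and
composition exactly). Peptides hitting both lists are assigned randomly
with the recorded seed. Within each peptide length, predictions sort by
descending confidence and the accepted set is the largest rank k whose
decoy/target ratio D_k/T_k stays below α (default 0.01); a stratum with no
decoy matches accepts all its targets. At desk scale this estimator is
noticeably optimistic when strata are small (D stays 0 until the first
decoy), which the error-control simulation in the test suite sizes around.

Single-nucleotide explainability of a substitution asks whether any codon
pair of the two residues differs at exactly one position in the standard
nuclear genetic code; stop codons are not allowed as intermediates. Two
enumerations are exposed: the 20 standard residues (150/380 = 39.5% of
ordered pairs explainable) and the 21 residues of the human reference
proteome including selenocysteine with its UGA recoding (162/420 = 38.6%).
The 21-residue figure is the package's reference value because matching
against the human proteome encounters selenoproteins. BLOSUM62 statistics
(42/380 = 11.05% positive off-diagonal entries) come from the canonical
matrix shipped with biopython.

## Synthetic data

The generator emulates just enough of peptide fragmentation to exercise
every pipeline stage: complete b/y ladders (b_i = N-terminal prefix mass +
proton, y_i = C-terminal suffix mass + water + proton; charge-2 fragments
added when the precursor charge is ≥ 2), log-normal intensities with the y
series drawn 2× higher on average than the b series (shape σ = 0.5),
Gaussian m/z jitter in ppm (default 5), uniform background noise peaks
(default 10 per spectrum) capped below the 20th percentile of signal
intensity, and independent fragment dropout (default 10%). Precursor charge
is drawn from {2: 0.55, 3: 0.34, 4: 0.11}, reflecting that roughly one in
ten precursors in large tryptic corpora carries charge 4+. Peptides default
to 6–20 residues, non-enzymatic (uniform C-terminal residue) or tryptic
(C-terminal K/R); 5% of peptides carry an N-terminal modification and
modifiable residues (M, N, Q) are substituted by their modified forms with
probability 3% so the full vocabulary is exercised.

What it does *not* model: real fragmentation physics (intensities carry no
sequence information beyond the b/y asymmetry), isotope envelopes, internal
and immonium ions, co-isolation, or chimeric spectra. Tests passing on this
generator demonstrate that the architecture, training loop, decoder, and
metrics are correct and that the model class can learn mass-ladder reading;
they do not certify accuracy on instrument data.

The balanced C-terminal sampler reproduces how a non-enzymatic training set
is assembled from tryptic-biased corpora: at most 100 spectra per unique
peptide, then up to a per-residue cap per C-terminal amino acid, both drawn
with the run seed.

## Desk-scale training study

The test suite trains a reduced model — 2 encoder + 2 decoder layers,
d = 64, 4 heads — on 20,000 noiseless synthetic spectra of length 6–10
peptides, with 500 validation and 1,000 test spectra from disjoint
peptides. Short runs need hotter optimization than the publication-scale
schedule: the desk run uses the pre-norm residual layout, peak learning
rate 3e-3, warmup capped at a tenth of total steps, gradient-norm clipping
at 5, and the intensity projection initialized 10× larger than Xavier so
the (unit-sum-normalized, hence individually tiny) intensities are visible
to attention from the start. These choices came from a grid over learning
rate, batch size, residual layout, and embedding variants on an 8,000
spectrum corpus.

Two results frame what this study can and cannot show, both computed by
the test suite on every run. On a reduced five-residue alphabet the same
model reads held-out mass ladders almost perfectly (validation token
accuracy above 0.95 within eight epochs), so the architecture, encodings,
decoder, and training loop are demonstrably correct end to end. On the
full 28-token vocabulary, the desk-scale schedule itself is the binding
constraint: after twelve epochs (~7,500 optimizer steps) held-out token
accuracy sits near 0.62 and beam-decoded peptide precision at full
coverage near 0.05, far below the 0.95/0.90 thresholds the corresponding
tests assert — those two tests fail under this schedule and are left
asserting the stated thresholds rather than weakened. The gap is a
matter of optimization steps, not model class: the method this package
implements is trained for days on GPUs at publication scale, and the
learning curves here are still rising when the schedule ends. Learning
rate, batch size, residual layout, feed-forward width, wavelength band,
embedding size, and embedding initialization were each varied without
changing this conclusion.

## Known limitations

* Training throughput is CPU-bound numpy; the publication-scale
  configuration is constructible (and its parameter count verifiable) but
  is not intended to be trained with this implementation.
* The decoder re-runs the full prefix at every step (no key/value cache);
  beam search cost grows quadratically in peptide length, immaterial at
  desk scale.
* The D_k/T_k accepted-set rule has a small-sample optimistic bias (no +1
  pseudocount), inherited from the procedure it reproduces.
* Only the linear-layer intensity embedding is implemented; a sinusoidal
  intensity variant is reported elsewhere to perform similarly.
* MGF is the only spectrum format read; mzML/mzXML are expected to be
  converted upstream.
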