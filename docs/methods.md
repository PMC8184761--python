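# Methods

`respectra` re-implements, at desk scale, an intensity-prediction-assisted
pipeline for identifying tryptic and non-tryptic (HLA) peptides from
tandem mass spectra: fragment annotation into a masked intensity tensor, a
recurrent intensity predictor trained with a spectral-angle loss,
feature-only semi-supervised target-decoy rescoring, a consecutive-filter
re-assessment of proposed proteasomally spliced peptides, and
position-weight-matrix motif validation. Everything is exercisable end to
end on synthetic spectra; no external data are required.

## The fragment tensor and its masking

All intensity information lives in a fixed-shape tensor of 29 fragment
positions x {b, y} x fragment charge 1-3 (174 entries). An entry is
*masked* (sentinel -1) exactly when it cannot exist: the position is at or
beyond the peptide length, or the fragment charge exceeds the precursor
charge. Valid entries are relative intensities, base-peak normalized so
the largest annotated fragment is 1. The flat vector layout is
position-major, b before y, charge ascending; it is the file contract for
prediction dumps.

Annotation matches theoretical b/y m/z values (monoisotopic masses to five
decimals; proton 1.0072765 Da, water 18.010565 Da) against observed peaks
at 25 ppm for Orbitrap (FTMS) spectra and 0.4 Da for ion-trap (ITMS)
spectra. The ITMS width is conventional ion-trap practice; only the FTMS
value is anchored externally. When several peaks fall inside a window the
most intense wins, ties broken by smaller m/z error; one observed peak may
serve several theoretical ions (no deduplication — the simplest contract,
stated explicitly). a-ions, internal ions and neutral losses may be
present in spectra but are never scored: the predictor covers b/y ions
only.

## Spectral contrast angle

Similarity between two tensors is the normalized spectral contrast angle
over the dimensions valid in both,

    SA = 1 - (2/pi) * arccos( <p_hat, o_hat> ),

with p_hat, o_hat the L2-normalized vectors and negative predictions
clipped to zero. SA is 1 iff the vectors are positively proportional. If
either vector is all zero, SA is defined as 0: a PSM whose predicted ions
find no observed signal earns no credit. `1 - SA` is also the training
loss; there the cosine is clamped to `[-1 + 1e-7, 1 - 1e-7]` so its
gradient at a perfect prediction is exactly zero instead of undefined
(arccos is singular at +/-1).

## The intensity predictor

The network is a recurrent encoder-decoder implemented on a small
in-repository reverse-mode autodiff engine (numpy, float64, CPU-only):

* peptide encoder: token embedding (20 residues plus oxidized-M and
  carbamidomethyl-C tokens, max length 30), a bidirectional GRU, a second
  GRU, additive-attention pooling, dropout;
* metadata encoder: one dense layer mapping the precursor-charge one-hot
  (6) and NCE/100 to the latent width; fusion by element-wise
  multiplication;
* decoder: the fused latent repeated over 29 steps, each step concatenated
  with a learned 8-dimensional positional embedding, through a
  bidirectional GRU with additive attention, and a shared dense head
  emitting 6 intensities (b/y x charge 1-3) per position.

Outputs are clipped to >= 0, masked entries restored to -1, and base-peak
normalized per spectrum. Because the loss is scale-invariant, the
attention softmax scaling is immaterial.

Training uses Adam under a triangular cyclic learning rate between 1e-7
and 1e-3, the upper limit decaying by 0.95 every 8 epochs; the half-cycle
is 4 epochs (the waveform itself is this package's choice — only the
limits and the decay are externally anchored). An optional restart phase
re-enters the cycle with upper limit 1e-4 for fine-tuning, mirroring the
restart used at publication scale. Early stopping monitors the test-set
loss and the best weights are restored. Desk defaults are 64 recurrent
units and batches of 16-128; the publication-scale 512 units pass through
the same configuration unchanged, so the architecture is faithful without
GPU-scale training.

Data hygiene mirrors the original protocol: PSM tables are restricted to
length 7-30 and precursor charge below 7, at most the top-3 scoring
spectra per (sequence, modification, charge, method, energy, analyzer)
group enter training, and the 70/20/10 train/test/holdout split is by
unmodified sequence so no sequence appears in two sets (asserted on every
split).

## Collision-energy calibration

Instruments drift, so the NCE at which predictions best match a dataset is
determined empirically: take a confident calibration set (by default the
top 1,000 PSMs by engine score), predict at every NCE on the 20-40 grid,
and pick the NCE maximizing the median SA (ties to the lower NCE). The
full median-SA curve is returned for audit.

## Retention time

A learned hydrophobicity model is out of reach at desk scale, so the RT
predictor is linear in residue composition and length, fit by least
squares. The residue-count columns sum exactly to the length column, so
the design is rank-deficient by construction; the minimum-norm solution is
used and only *predictions* are identifiable, not individual
coefficients. Predicted times are mapped onto a run by a repeated-median
(Siegel) robust line; the agreement metric delta-iRT95 is the 95th
percentile (linear interpolation) of absolute residuals. The |observed -
predicted| feature enters rescoring exactly as a learned predictor's
would, with a missingness indicator when no prediction exists.

## Rescoring

The feature vector per PSM contains only quantities computable from the
prediction and the annotation: SA, Pearson and Spearman correlations (with
a definedness indicator; degenerate cases map to 0), the fraction of
predicted ions with observed signal, the fraction of total ion current
annotated, matched b/y counts, |delta RT|, |precursor ppm error|, length,
and the charge one-hot. Search-engine scores are rejected by name if
supplied — separation must come from prediction agreement alone.

Semi-supervised learning follows the Percolator scheme with an L2
logistic-regression discriminant: per cross-validation fold (3 folds),
initialize from the single feature direction maximizing accepted targets
at q <= 0.01, then iterate up to 10 times { positives = targets at
q <= 0.01 under current scores, negatives = all decoys; fit; rescore }.
Within a fold the scorer actually kept is the best iterate (including the
initial direction) by accepted targets on the training split, so the
iteration cannot do worse than the raw feature ranking. Each PSM is scored
by the fold that never saw it; fold scores are standardized against their
decoy population before pooling so that scores — including those of a
model transferred to another engine's PSM list — live on one comparable
scale. Features that are numerically constant in training are left
unscaled rather than amplifying float noise on transfer.

q-values use target-decoy competition with the conservative +1 numerator:
FDR(s) = (#decoys >= s + 1) / max(1, #targets >= s), evaluated per score
threshold (tied decoys count against tied targets), then monotonized from
the lowest score upward. Peptide-level q-values keep the best PSM per
modified sequence (charge excluded) and repeat the competition on that
reduced list. Analyses optimize 1% FDR at both levels.

## Spliced-peptide re-assessment

A proposed spliced peptide is audited by four consecutive filters; a
candidate is charged to the first filter that rejects it and accounting
always conserves `total = rejections + retained + non-assessable`
(candidates without a rescoring result are counted separately, never
silently kept):

1. not confident after feature-only rescoring (q above the threshold);
2. I/L isomer of a canonical peptide (checked against the candidate's own
   competitors *and* a supplied canonical universe) — indistinguishable by
   mass spectrometry;
3. a canonical competitor PSM scores at least as high on the shared scale;
4. the spliced score beats the canonical one by no more than a margin
   delta (default 1.0 standardized score units; "substantially better" has
   no published number, and the showcase ambiguity the default must catch
   has a gap of 0.4, so the margin is exposed as a tunable that must
   exceed 0.4).

The canonical control applies filters 1 and 3 only. Cross-engine best-PSM
ranking resolves ties in favour of the canonical hypothesis, then the
lexicographically smaller sequence.

## Motifs

Per-length PWMs are column-stochastic frequency matrices with an optional
additive pseudocount (0 for display, 0.5 when scoring unseen residues).
The emission probability of a peptide is the sum of its residue
frequencies at the top-5 positions ranked by column maximum — anchor-like
positions dominate, making 8-11-mer scores comparable; per-allele values
average across lengths. Motif distance is the mean across positions of
the base-2 Jensen-Shannon divergence between columns (the aggregation and
log base are this package's choice, so no published single-number motif
distance is claimed reproducible).

## The synthetic surface

The generator defines the study conditions for every test. Fragmentation
is a deterministic rule encoding three real phenomena so that model
recovery is meaningful rather than vacuous: a centred Gaussian cleavage
propensity along the backbone, tripled N-terminal to proline; y over b
preference (2:1) with b suppressed (x0.3) when only the complementary y
ion carries a basic residue; fragment-charge weights
exp(-|k - (1 + n_basic/2)|) with n_basic counted in the fragment; and an
NCE tilt (m_frag/m_prec)^(-0.5 (NCE-30)/10) moving intensity toward small
fragments at high energy. Constants are arbitrary but fixed.

Rendering adds 5 ppm Gaussian m/z jitter, log-normal intensity scatter
(sigma 0.3), and Poisson-placed uniform noise peaks (1 per 100 Th) —
defaults emulating a clean Orbitrap HCD run. Decoys are full sequence
reversals (non-tryptic peptides have no C-terminal anchor to preserve);
palindromes get one internal swap. Confusion pairs embed the isobaric
substitutions GVA/NL, GG/N, GA/Q and I/L into random canonical sequences
and render the spectrum from the canonical truth, so the splice audit runs
against known ground truth. The PSM benchmark draws false targets and
decoys from one distribution (exchangeability), making the realized
false-discovery proportion exactly computable.

In the noiseless limit the renderer and annotator are exact inverses —
the keystone oracle — *except* for peptides whose theoretical fragment
windows overlap (coincident peaks merge physically); a collision screen
excludes such peptides where exactness is asserted. Every generator is a
pure function of (config, seed).

What the simulator does not emulate: mobile-proton chemistry, isotope
envelopes, chimeric spectra, real retention behaviour, engine-specific
score distributions. Passing the recovery experiments therefore shows the
machinery is correct and trainable, not that the desk-scale network
matches publication-scale accuracy on real data.

## Problem sizes and numerical choices

The recovery experiment trains on 2,000 noiseless spectra (70/20/10
split, batch 16, up to 50 epochs with a restart at epoch 36) and requires
held-out median SA >= 0.9; CE calibration uses 500 noisy PSMs and must
recover NCE 30 +/- 1; FDR calibration pools ten 1,200-PSM benchmarks; the
splice audit uses 100 confusion pairs over a 400-target canonical
background. These sizes keep any single experiment within minutes on one
CPU core while leaving each check statistically meaningful.

Degenerate inputs are contracts, not crashes: all-zero tensors normalize
to themselves and score SA 0; empty groups are absent from summaries; an
all-decoy list, a mixed-length PWM set, a degenerate RT alignment and a
missing mandatory column are hard errors naming the offender.

## Known limitations

* The desk-scale network shares the architecture family, loss and
  schedule of the publication-scale model but not its capacity or data;
  its weights and real-data accuracy are not comparable.
* The exact feature set of the published rescoring workflow is not
  enumerated anywhere; the set here is a reasonable reconstruction under
  the "no engine scores" constraint, and parity is not claimed.
* The rescoring discriminant is logistic regression rather than a linear
  SVM; PIN export keeps the external Percolator program usable for parity
  checks.
* Stage-iii competitor comparison is per spectrum only; whether scores
  should also compete across spectra of the same peptide is left open.
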