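# Methods

## Problem and data model

An identified N-glycopeptide is written `PEPTIDE_h_n_f_s`, the four integers
counting Hex, HexNAc, Fuc and Sia residues. One MS/MS spectrum assigned to
one such identification is a glycopeptide-spectrum match (GSM). The task is
to assign each GSM one of four fucosylation classes — `none`, `core`
(alpha-1,6 on the innermost GlcNAc), `outer` (alpha-1,3/4 on an antenna) or
`dual` (both) — from the CID fragment pattern alone.

The physical basis is the fate of fucose in glycosidic fragmentation. Core
fucose is retained on the peptide-bearing Y fragments, so core-fucosylated
GSMs show Yn/YnF pairs (Y1 = peptide+HexNAc ... Y4 = peptide+2HexNAc+2Hex,
each with a +146.0579 Da partner). Outer fucose leaves with the glycan-only
oxonium B fragments, pairing B2 (Hex-HexNAc, m/z 366.14) with B2F (512.20)
and B3S (Hex-HexNAc-Sia, 657.23) with B3SF (803.29). Mass arithmetic uses
fixed monoisotopic residue masses (Hex 162.05282, HexNAc 203.07937, Fuc
146.05791, NeuAc 291.09542, proton 1.00728, water 18.01056); peptide masses
come from the standard residue-mass table with carbamidomethyl cysteine
(+57.02146) as the default fixed modification. All 14 diagnostic ions are
matched singly charged; multiply charged Y-ion matching is deliberately not
attempted.

## Feature extraction

For each GSM the 14 theoretical ion m/z values are matched against the
spectrum within a ±0.02 Da window. A peak qualifies only when its intensity
is at least `snr_min` (default 3) times the spectrum noise level, taken as
the **median intensity of the nonzero peaks** — a robust, parameter-free
estimate that is accurate whenever noise peaks dominate the peak count, as
they do in real centroided CID spectra. Among qualifying peaks the most
intense wins; intensity ties break to the lower m/z. Matched intensities
are divided by the spectrum base peak, giving features in [0, 1] that are
invariant to overall intensity scaling; an unmatched ion scores 0.
Normalisation by the sum of the 14 matched intensities is available as an
alternative (`normalization="matched_sum"`).

Two caveats are inherent to these conventions. First, the median-based
noise estimate is meaningless for a spectrum that contains *only* signal
peaks (it then equals the signal level and the S/N gate removes
everything); the generator-closure tests therefore run extraction with
`snr_min=0` on noiseless spectra, which contain no noise population by
construction. Second, the "monoisotopic peak" is taken at face value — no
isotope-envelope verification is done, because centroided input gives no
reliable envelope to verify against.

## Classifiers

Both families map the 14 features to a probability simplex over the fixed
class order (none, core, outer, dual).

**Network family.** A fully connected MLP: 14 inputs, `n_layers` hidden
layers of `n_nodes` ReLU units, 4 softmax outputs (softmax rather than a
per-output sigmoid — a categorical distribution is required for the Pscore
below). Weights are Xavier-initialised (Gaussian, sd = sqrt(2/(fan_in +
fan_out))) from a seeded generator; training is full-batch gradient descent
on the cross-entropy at learning rate 0.02 for a fixed number of epochs,
with inverted dropout (keep probability 0.75) on the hidden activations
during training only. `0.75` is interpreted as the *keep* probability, the
convention of the framework generation this architecture family comes
from. Everything is driven by `numpy` from a single `default_rng(seed)`,
so training is bit-reproducible. The default search grid crosses nodes
{8, 16, 32, 64, 128}, hidden layers {3, 4, 5}, epochs {10, 100, 500, 1000,
2000, 5000, 10000, 20000} and 10 replicate seeds: 1,200 candidates.

**Margin family.** A linear-kernel C-classification SVM in probability
mode (scikit-learn `SVC`, one-vs-one with pairwise Platt calibration; the
seed controls the calibration's internal CV split). The default cost grid
reproduces a four-stage search — powers of two 2^-5...2^15, then 2^0...2^6,
then integers 4...16, then 8.0...11.0 in 0.1 steps — deduplicated to 52
distinct values, crossed with a fixed panel of 20 seeds (including 435,
the conventional best seed for the default configuration): 1,040
candidates.

## Decoy scoring, FDR and model selection

Each prediction is scored by `Pscore = −ln(1 − (P1 − P2))` with P1, P2 the
two largest class probabilities; the gap is clamped at `1 − 1e−12`, so the
score is finite (≤ ~27.63) and strictly increasing in the gap. Decoy GSMs
are built by permuting the 14 values *within* each feature vector,
uniformly at random, which destroys the ion-pairing structure while
conserving the intensity multiset exactly; five decoy replicates are drawn
and each GSM's decoy Pscore is their mean.

Targets vs. decoys are compared two ways:

* **AUC** of the ROC curve with targets as positives (equal to the
  Mann–Whitney statistic, ties counted 1/2);
* an **FDR cutoff**: `FDR(t) = #{decoy ≥ t} / max(1, #{target ≥ t})`, and
  the reported cutoff is the smallest observed target score with
  FDR < q (default q = 0.01). No pi0 correction is applied. When no
  threshold qualifies the cutoff is +inf and nothing passes.

Each candidate model is summarised by accuracy on the held-out labelled
set, the target–decoy AUC there, and the **Euclidean length**
`EL = sqrt(accuracy² + AUC²)`; the best model per family is the EL argmax
(ties to the lowest index). Decoys are always drawn from the same GSM set
that is being filtered, so each set (train / test / unknown) gets its own
cutoff.

**Consensus.** A GSM receives a final class only if both family winners
predict the same class *and* it passes the FDR filter in at least one
family (the default `union` rule; a stricter `intersection` rule is a
config switch). In `evaluate()`, accuracy counts unclassified GSMs as
errors, while sensitivity — correct / (correct + incorrect) — is computed
over the consensus-classified GSMs only, mirroring the usual
true-positive / false-negative bookkeeping for a filtered result list.

## Synthetic data generator

The generator is the package's study-condition definition: it emulates the
diagnostic-ion logic of real CID spectra well enough that every downstream
stage (extraction, training, decoy FDR, consensus) is exercised honestly.

Each class template is the panel of diagnostic ions the class may show:
backbone ions (B2, B3, B3S, Y1–Y4) for everyone; YnF added for `core`;
B-series F ions for `outer`; both for `dual`. At generation time the panel
is intersected with the ions *feasible* for the composition (B3S/B3SF need
a sialic acid, Y4 needs two hexoses, F ions need fucose), so e.g. an
asialo glycopeptide never shows B3S. Peaks are placed at theoretical m/z
with Gaussian jitter (sd 0.004 Da, truncated to ±0.01 so a peak never
leaves its match window) and intensities drawn from per-ion log-normal
laws. Thirty noise peaks per spectrum, log-normal around 2 a.u., are
placed uniformly in m/z but kept out of the diagnostic windows; they anchor
the median-noise estimate the S/N gate relies on.

The default intensity laws have two tiers. The small, efficiently formed
fragments — B2, B2F, B3S, B3SF, Y1, Y1F, Y2, Y2F, Y3F, Y4F — are strong
(log-mean 100 a.u., sigma 0.15, i.e. ~15% replicate CV). The larger
intermediates B3, B3F, Y3 and Y4 are an order of magnitude weaker (12–25
a.u., sigma 0.3), sitting near the S/N detection limit, so their presence
varies naturally from spectrum to spectrum without any explicit dropout
(an explicit per-ion `dropout_prob` knob exists, default 0).

This two-tier design is load-bearing for the decoy scheme, and the reason
deserves recording. Within-vector permutation decoys can only be
distinguished from targets by features the permutation breaks. If every
present ion had the same intensity scale, a fully occupied (dual-like)
vector would be nearly *exchangeable* across slots — its permutations
would be statistically indistinguishable from genuine dual vectors, no
classifier could score them down, and the target–decoy separation the
filtering layer depends on would be impossible for ~15% of decoys.
Conversely, a steep intensity ladder across all slots backfires: a
permutation then drops a dominant backbone intensity into a fucose slot
and produces *stronger*-than-trained class evidence, which a
margin/softmax model extrapolates into higher, not lower, confidence. The
realistic middle ground — uniform strong evidence ions plus a weak tier
near the detection limit — breaks exchangeability in the direction models
actually notice: a permutation moves a near-threshold intensity into a
slot where every training example is strong, the input pattern falls off
the training manifold toward the low-confidence interior, and decoy
Pscores drop. Under these defaults both families reach held-out accuracy
~1.0 and target–decoy AUC ≥ 0.99 across seeds, the qualitative regime the
method is designed for.

Data sets default to the class mix of a curated standard-protein training
set (39% none, 25% core, 21% outer, 15% dual) and draw compositions so
that antennarity correlates with class — outer/dual favour tri/tetra-
antennary compositions, none/core favour mono/bi/hybrid — with a
configurable bias (default 0.8). Peptide backbones come from a pool of six
tryptic plasma-glycoprotein sequences. Fucose counts are 0/1/1/2 for
none/core/outer/dual.

The **oracle classifier** encodes the pairing rule directly: any B-series
F ion above threshold is outer evidence, any YnF is core evidence, both
give dual, neither none. It is not the learned classifier — it is a
falsifiable ground-truth contract: on noiseless spectra (zero jitter,
zero intensity spread, zero noise peaks) the generate → extract → oracle
loop must return the template label exhaustively over the peptide ×
composition grid, and the learned models are validated against the
generator's hidden labels rather than against themselves.

What the generator does **not** model: isotopic envelopes and profile peak
shapes (spectra are ideal centroids), retention time, chimeric spectra,
in-source fucose migration (which in real data can paint weak false F-ion
signals and is the main real-world threat to the pairing logic), and
intensity correlations between paired ions. Passing tests on synthetic
data therefore demonstrate the correctness and internal consistency of
the pipeline, not field performance on real plasma data.

## Problem sizes and runtime conventions

The test suite trains reduced configurations chosen to keep the full run
in tens of seconds: the label-recovery check uses a 400-GSM training set
and a 400-GSM held-out set at default noise, one network (64 nodes, 4
hidden layers, 2,000 epochs) and the margin costs {1.0, 8.7} at seed 435,
with the usual 5-replicate decoys and q = 0.01. The scoring primitives
(`roc_auc`, `fdr_cutoff`) are verified against brute-force all-pairs /
exhaustive-threshold oracles on hundreds of random small instances, and
decoy conservation is checked on 1,000 random vectors. Property tests run
under fixed hypothesis seeds; every stochastic component takes an explicit
integer seed and is bit-reproducible.

## Numerical conventions and degenerate inputs

* Pscore clamp: gap ≤ 1 − 1e−12, so Pscore ≤ −ln(1e−12) ≈ 27.631.
* Classification ties break to the earliest class in (none, core, outer,
  dual); peak-match intensity ties break to lower m/z.
* Empty spectrum → all-zero feature vector (not an error); all-zero
  spectrum noise → 0, so every peak passes S/N.
* Empty training set, empty cost grid, empty target-score list, mismatched
  GSM universes in consensus → errors; single-class training set → warning
  but a valid fit.
* `fdr_cutoff` with no qualifying threshold → (+inf, 0).
* MGF round-trips are exact at 5 decimal places; duplicate spectrum titles
  are rejected at read time.

## Known limitations

* The FDR estimate is the raw decoy/target count ratio; with few GSMs it
  is coarse, and a +inf cutoff (empty filtered set) is possible.
* Calibrated margin-family probabilities are only as good as Platt
  scaling on small per-class counts; with very small training sets the
  probability mode can behave erratically even when raw classification is
  perfect.
* The antennarity grouping (antennae = HexNAc − 2; hybrid when Hex ≥
  antennae + 4 with ≥ 1 antenna; hybrid tested before the plain counts,
  which would otherwise shadow it) is a composition-level heuristic, not a
  structure determination.
* Fucose position within a class (which antenna carries the Lewis fucose)
  is out of scope, as is glycan topology generally.
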