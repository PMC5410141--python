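# Methods

## Model

A candidate PTM site is represented by two views: its 21-residue
peptide window and its interaction profile — the binary row of the
site × PTM adjacency matrix *A* recording which modifications the site
is experimentally known to carry. Classification is a soft-margin SVM
over a precomputed Gram matrix

    K = β₁ K_seq + β₂ K_GIP ,   β_d ≥ 0,

where `K_seq` is the min-max-normalized positionwise BLOSUM62 sum over
the 21 aligned window positions and `K_GIP(i,j) = exp(−γ‖A_i − A_j‖²)`
is a Gaussian kernel on interaction profiles (for binary profiles the
squared Euclidean distance is the Hamming distance). The model assumes
that local sequence context and modification co-occurrence each carry
class signal and that a non-negative combination of the two kernels
preserves both; it treats every PTM/kinase-group task as an
independent binary problem.

## Parameters

| parameter | default | meaning |
|---|---|---|
| flank | 10 residues | window half-width; windows are 2·flank+1 long |
| γ (gamma) | 0.001 | GIP bandwidth; small values keep the kernel near 1 and let profile differences act as a gentle ranking signal rather than a hard partition |
| β (betas) | (0.5, 0.5) | kernel weights; (1,0)/(0,1) recover single-kernel models; an equal split is the uninformative default and can be grid-searched externally |
| C | 1.0 | SVM regularization (the solver default) |
| balanced | true | per-class penalties C_± = C·N/(2·N_±), i.e. inverse class frequency; reduces to uniform C on balanced data |
| folds × repeats | 10 × 10 | cross-validation protocol; metrics are computed on scores pooled within a repeat and averaged over repeats |

Terminal positions outside a protein are padded with `X` and scored
through the BLOSUM62 X row (X–X = −1), which keeps the sequence sum
defined for sites near termini with a published score set; rare
residues U/O are remapped to X for the same reason. Coordinates are
1-based throughout.

## Cross-validation and leakage control

The sequence similarity matrix is label-free and computed once
globally. Per fold, its min/max normalization constants are taken from
the training block only and applied to the train–test cross block with
clamping to [0, 1]; this prevents test-to-train information flow, and
because the map is monotone it cannot reorder training similarities.
The adjacency matrix is masked per fold: the target-PTM column is
zeroed for held-out sites (their other annotations are retained —
cross-PTM relationships are legitimate, already-known inputs) and the
GIP kernel is recomputed. Training rows keep all annotations,
including the target column. Folds are stratified by class so every
training fold contains both classes even for rare PTMs; per-repeat
fold seeds derive deterministically from one master seed.

A dedicated audit (`evaluate_fold`) exposes the per-fold kernels so
tests can verify, bitwise, that randomizing held-out target labels and
target-column annotations changes no training kernel entry and no test
score.

## Numerical choices

* Symmetry of kernel matrices is enforced to 1e−12; PSD assertions use
  −1e−10 on the smallest eigenvalue.
* Min-max normalization of a BLOSUM62 sum matrix does not guarantee
  positive semi-definiteness; an optional eigenvalue-clipping repair
  (`psd_repair`) is available and off by default, since libsvm-style
  solvers accept slightly indefinite Gram matrices in practice.
* ROC curves place one vertex per distinct score (ties grouped);
  trapezoidal AUC then equals the Mann–Whitney concordance probability
  with ties counted ½ — the unique tie convention with that property.
* Specificity-anchored thresholds are the smallest observed score
  whose empirical specificity reaches the target (score ≥ threshold ⇒
  positive); an unreachable target returns +∞ with a flag.
* Metrics with zero denominators are reported as undefined and
  flagged, never coerced to 0, because silent zeros corrupt averages;
  a repeat-average is undefined if any contributing repeat is.
* Ties at decision value exactly 0 are classified positive.
* Platt probabilities use the sigmoid `P(+1|f) = 1/(1+exp(−(af+b)))`
  fitted by maximum likelihood (regularized targets) on stratified
  5-fold out-of-fold decision values with a fixed seed. Fitting our
  own sigmoid rather than using the solver's built-in calibration
  keeps the probability map explicit, deterministic and serializable.
* Model files are versioned JSON; round-trips reproduce decision
  values exactly because coefficients are stored at full precision.

## Synthetic data

The generator emulates the two regularities the method exploits.
Positives draw each consensus position of a fixed fully-specified
21-mer with total match probability `match_prob` (the internal forcing
rate is corrected for background coincidences, so `match_prob` equal to
the background frequency is an exact null); negatives are background
draws with the correct central residue. Positives carry each of 7
helper annotations with probability 0.6, negatives with 0.05; the
target column marks positives and is masked during CV. Background
residue frequencies default to uniform over the 20 standard residues,
which makes the null calibration analytic; a natural-abundance table
can be supplied instead. Default study conditions are 400 sites, half
positive — large enough for stable ten-fold metrics, small enough that
the full repeated protocol runs in seconds.

What the generator does **not** emulate: the extreme class imbalance of
real PTM databases, homology-induced redundancy between sites (real
evaluations should group homologous proteins across folds), kinase
family-specific motif catalogs, and position-specific residue
composition. Passing tests therefore demonstrate correctness of the
machinery and calibration of the protocol, not field performance on
curated databases.

## Design choices where the design was open

* **Normalization scope.** Train-block-only min/max with clamped
  out-of-sample application (rather than normalizing over all sites
  jointly) was chosen to keep the evaluation leakage-free; it can
  shift absolute kernel values but not training-block orderings.
* **Masking semantics.** Only (held-out rows × target column) is
  zeroed. Alternatives — zeroing whole rows, or all target entries —
  discard known cross-PTM evidence that the method is explicitly
  designed to use.
* **Aggregation.** Metrics are computed on within-repeat pooled scores
  and averaged across repeats; per-fold metrics are available behind a
  flag, since per-fold AUC averaging is the other convention in use.
* **β search.** No internal β optimization is performed; the default
  is uninformative and `signal_sweep` shows single-kernel baselines
  alongside the combination for any dataset.

## Known limitations

* The GIP kernel at γ = 0.001 is numerically flat (entries in roughly
  [0.99, 1]); class signal survives in the decision function because
  the constant component cancels against Σaᵢyᵢ = 0, but decision
  values for GIP-only models are small and their default-threshold
  confusion metrics are conservative even when ranking (AUC) is
  excellent. Specificity-anchored thresholds avoid this artifact.
* Positive semi-definiteness of `K_seq` is assumed, not guaranteed
  (see above).
* Candidate ranking treats the candidate's target-column annotation as
  0 by definition; candidates already annotated with the target PTM
  should not be scored as candidates.
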