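# Methods

This note records the model, the numerical choices behind it, and what
the synthetic benchmark does and does not demonstrate.

## Features

Every transcript is mapped to a fixed-order vector of 1365 values:
4 nucleotide frequencies + GC, 4 codon position biases, 12 ORF
statistics, and k-mer frequency blocks of size 64/256/1024 for
k = 3/4/5. Conventions for inputs the formulas leave undefined:

* **ORF definition.** Forward strand only; start = ATG; stops =
  TAA/TAG/TGA; each ATG pairs with its *nearest* in-frame stop
  downstream; nested starts each yield their own ORF sharing the stop;
  an ATG with no downstream in-frame stop contributes to the start-codon
  count but yields no ORF. Under this definition the ORF frequency
  (#ORF / #ATG) always lies in [0, 1]. Codon windows containing N never
  match a start or stop pattern.
* **Start/end codon distribution.** Interpreted as the mean and
  population SD of the *relative positions* (index / transcript length)
  of ORF starts and ends — the scale-free reading consistent with every
  other length-normalized feature. This is a choice, not an established
  convention.
* **Degenerate denominators.** Codon position bias of an absent base,
  frame bias and ORF statistics of a transcript with no ORF, ORF
  frequency with no ATG, and k-mer blocks with no valid (N-free) window
  are all 0. `log10(longest ORF length)` is 0 when no ORF exists.
  SDs are population SDs (defined for a single ORF).
* **N handling.** N is kept in the sequence; composition denominators
  count non-N positions only; k-mer windows containing N are skipped and
  the block is renormalized over the counted windows.

## Network

A 10×10 rectangular, non-toroidal SOM grid (Manhattan topology; radius
r = rows + cols − 2 = 18) under two sigmoid perceptrons. Training-time
unit activations are neighborhood-smoothed,

    a_u(x)      = Σ_u′ exp(−½‖x − w_u′‖²) · σ_t(u′, u)
    σ_t(u′, u)  = exp(−d(u′,u)² / (α (1 − t/T) r)),

so credit propagates across the map early and the smoothing vanishes as
t → T; prediction drops the neighborhood term entirely. The decay
factor (1 − t/T) is floored at 1e−8 so the kernel is defined at the
final iteration. BMU ties resolve to the lowest unit index.

**Loss.** Cross-entropy for independent sigmoid outputs summed over
both perceptrons, plus an L2 penalty on the output weights:

    L = −(1/N) Σ_i Σ_l [ y_il ln o_il + (1 − y_il) ln(1 − o_il) ] + λ Σ ‖w_out‖².

The two-sided form matters: a one-sided cross-entropy (−Σ y ln o alone)
over unnormalized sigmoids has a degenerate global optimum in which the
unregularized biases push *both* outputs to 1 for every sample — the
loss reaches ≈ 0 with zero discrimination, and we observed exactly this
collapse (output spread ~1e−16, chance accuracy) before adopting the
two-sided form. Outputs are clipped to [1e−12, 1 − 1e−12] before the
logarithm.

**Gradients.** Output-weight and bias gradients are exact
(`−(1/N) Σ (y − o) a + 2λw`; the test suite verifies them against
central finite differences to ~1e−9 relative error). The prototype
gradient deliberately routes the error through each sample's best
matching unit only,

    ∂L/∂w_u = −(1/N) Σ_i [Σ_l (y_il − o_il)] σ_t(BMU(x_i), u)
              · exp(−½‖x_i − w_u‖²) (x_i − w_u),

a simplification of the full derivative of the neighborhood-smoothed
activation (which would also carry the output weights). It is not the
exact gradient, so it is tested *directionally*: in the regime the
unsupervised initialization produces (samples clustered at
well-separated prototypes), a 1e−4 step along the negative direction
never increased the loss in any tested instance.

**Optimizer.** `w ← w − μ1 (μ2 acc + ∇L)` with μ1 = 0.05, μ2 = 0.25.
The accumulator is a geometrically decayed sum, `acc ← μ2 acc + ∇L`.
A raw (undecayed) running sum is available via `momentum_mode="sum"`
but is a frictionless heavy-ball: its loss traces oscillate over orders
of magnitude and the early-stopping rule then samples an arbitrary
point of the oscillation, which made end-to-end accuracy irreproducible
(0.49–1.00 under ppm-level input perturbations). The decayed form was
stable in every run tried.

**Schedule and stopping.** One iteration consumes one batch (default
100), taken as sequential slices of a seed-shuffled order, cycling.
Training stops at 10 000 iterations or as soon as two consecutive batch
losses differ by less than 1e−6; the stop reason and full loss trace
are stored in the model archive. The grid is initialized by 10 epochs
of classical unsupervised Kohonen learning (per-sample updates,
neighborhood `exp(−d²/(r(1 − t/T)))`, learning rate linear 0.5 → 0.01,
prototypes started as ±0.01 uniform noise around the feature mean).

## Feature scaling = kernel bandwidth

The activation kernel `exp(−½‖x − w‖²)` has a fixed bandwidth, so the
feature scale *is* the kernel bandwidth, and two failure modes bracket
the working regime:

* unscaled, the raw ORF-length mean/SD features (nucleotide units,
  variance ~2e4) drive every squared distance to hundreds and the
  kernel underflows to 0 for all units;
* fully min-max scaled, the ~1300 k-mer dimensions — individually nearly
  pure sampling noise — are each stretched to [0, 1], the noise floor of
  the squared distance rises to O(50), and the ~20 informative features
  no longer shape the geometry (SOM units stop being class-pure).

The default scaler therefore (1) min-max scales **only** features whose
training range exceeds 1, leaving frequency-type features at their
natural scale, and (2) divides all features by one global factor chosen
by the median heuristic so that the median squared pairwise distance
between training samples is 2 (a median pair has kernel value e^−1).
Both parameters are fitted on the training set only and serialized with
the model. Scaling can be disabled (`scale=False`), which is only
sensible for pre-scaled inputs.

## Rejection and metrics

ψ(x) = rejected if `|o_coding − o_noncoding| < β` (strict — equality is
kept), else argmax with ties to non-coding. β = 0 rejects nothing;
β = 1 rejects everything (sigmoid outputs are in the open interval).
The default β = 0.7 is a deliberately conservative cross-dataset
choice; `somcoding.cli.SPECIES_BETA_PRESETS` documents per-dataset
presets in the 0.1–0.8 range for species-specific models (lower for
compact microbial transcriptomes, higher for complex eukaryotic ones).
Accuracy, sensitivity and specificity are computed on non-rejected
records with non-coding as the positive class; a metric with a zero
denominator is reported as missing (None/NaN), never silently 0, so an
all-rejected evaluation is distinguishable from a failing one.

## Synthetic benchmark

The generator produces three regimes:

* **coding-like** — one embedded ATG…stop ORF covering ~85% of the
  transcript, body codons drawn from a positionally skewed distribution
  over the 61 sense codons (bias strength 0.75), uniform flanks;
* **non-coding-like** — uniform (optionally Markov-1) random sequence;
  stop codons are left unpruned, so these transcripts naturally show
  many short ORFs, high ORF frequency and low longest-ORF coverage;
* **ambiguous** (off by default) — a ~50%-coverage unbiased ORF in
  random sequence, mimicking boundary transcripts; an
  `ambiguity_fraction` of each class comes from this regime while
  keeping its class label.

Defaults are 500 + 500 transcripts of 300–1500 nt, deterministic under
a fixed seed. Problem sizes used by the test suite and the acceptance
script (70/30 split of 1000 transcripts; 20 gradient instances; 200–1000
oracle sequences) were chosen so a full run completes in minutes on one
CPU.

What passing tests show: the pipeline separates the two regimes
essentially perfectly (held-out accuracy ≥ 0.95, typically 1.0), the
rejection rule concentrates abstentions on label-mixed map units, and
everything is bitwise reproducible. What they do not show: performance
on real transcriptomes. Real coding/non-coding contrasts are weaker and
confounded (pseudogenes, short CDSs, UTR composition, lineage-specific
codon usage), real ncRNA classes are heterogeneous, and the synthetic
flanks are compositionally unrealistic. Results here validate the
implementation, not the biology.

## Known limitations

* Forward-strand ORFs only; IUPAC ambiguity codes other than N are
  rejected at input.
* The prototype gradient is the documented BMU-path simplification, not
  the exact derivative.
* The early-stopping rule compares losses of *different* consecutive
  batches and can fire early on easy data; the stop reason is recorded
  so this is auditable.
* No automatic β selection; the threshold is application-dependent.
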