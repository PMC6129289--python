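# somcoding

Discriminating coding RNAs from non-coding RNAs (ncRNAs) is a routine
first step in transcriptome annotation: given assembled transcripts and
no protein database, decide for each sequence whether it is likely to be
translated. `somcoding` implements an alignment-free classifier for this
task built around a **supervised self-organizing map (SOM) with an
ambiguity-rejection option**. Instead of forcing every transcript into
one of the two classes, the classifier abstains on transcripts whose
evidence is genuinely mixed — and, because the hidden layer is a SOM,
those ambiguous transcripts can be *located* on a 2-D map relative to
the coding and non-coding regions and inspected feature by feature.

It is intended for bioinformaticians who want a trainable, fast,
database-free coding-potential tool whose "don't know" answers are a
feature rather than a failure mode.

## Model

Each transcript is summarized by a fixed 1365-dimensional feature vector
*x*: nucleotide and GC frequencies, the codon position bias
`X_pos = min(X1,X2,X3)/max(X1,X2,X3)` for each base X, twelve open
reading frame (ORF) statistics (coverage and log10 length of the longest
ORF; mean/SD of the lengths, coverages, start and end positions of all
ORFs; frame bias `1 − min_f |ORF_f| / max_f |ORF_f|`; ORF frequency
`#ORF / #ATG`), and k-mer frequencies for k = 3, 4, 5.

The network has three layers:

* a **SOM hidden layer** — a 10×10 grid of prototype vectors
  `w_u ∈ R^1365`, initialized by classical unsupervised Kohonen learning
  (BMU(x) = argmin_u ‖w_u − x‖, Gaussian neighborhood over the Manhattan
  grid distance);
* two **sigmoid perceptrons** (coding, non-coding) fully connected to
  the grid: `o_l = sig(Σ_u w_ul a_u(x) + b_l)`.

During supervised training the unit activation is neighborhood-smoothed,
`a_u(x) = Σ_u′ exp(−½‖x − w_u′‖²) σ_t(u′,u)` with
`σ_t(u′,u) = exp(−d(u′,u)² / (α(1 − t/T) r))`, and the whole network
(prototypes, output weights, biases) is trained by backpropagation of a
cross-entropy + L2 loss with a momentum optimizer. At prediction time
the neighborhood term vanishes, `a′_u(x) = exp(−½‖x − w_u‖²)`, and the
class is the larger output. A prediction is **rejected** when
`|o_coding − o_noncoding| < β` for a threshold β (default 0.7): metrics
are then computed on the non-rejected transcripts only, with the
non-coding class as the positive class.

## Worked example

The package ships a synthetic-data generator that emulates the contrast
the classifier exploits — coding-like transcripts with one long,
codon-biased ORF versus non-coding-like transcripts with many short
scattered ORFs:

```sh
somcoding simulate --out-prefix sim --seed 7
somcoding train sim.coding.fasta sim.noncoding.fasta --out-model model.somc --seed 7
somcoding predict sim.noncoding.fasta --model model.somc --beta 0.7 --out-tsv pred.tsv
somcoding evaluate pred.tsv sim.labels.tsv --out-report report.tsv --out-sweep sweep.tsv
```

which logs

```
INFO somcoding: wrote 500 coding + 500 noncoding records
INFO somcoding: trained 10000 iterations, stopped by max_iterations, final loss 0.0417
INFO somcoding: 500 transcripts, 12 rejected at beta=0.70
INFO somcoding: accuracy=1.0 reject_rate=0.024
```

`pred.tsv` holds one row per transcript with both perceptron outputs,
the decision and the transcript's best-matching-unit coordinates:

```
id              output_coding   output_noncoding  predicted_class  bmu_row  bmu_col
noncoding_0000  0.0009330582167 0.9990734481      noncoding        6        9
noncoding_0001  0.0005045179665 0.9994982481      noncoding        7        8
```

and `report.tsv` the confusion counts and metrics on the non-rejected
rows — here all 488 kept predictions are correct and 12/500 (2.4%) are
rejected; specificity is reported as *missing* (not 0) because this
FASTA contains no coding transcripts:

```
beta  TP   TN  FP  FN  accuracy  sensitivity  specificity  reject_rate
      488  0   0   0   1.0       1.0                       0.024
```

`somcoding inspect` exports the per-unit label/decision counts and
prototype feature profiles (tables + heatmaps); on this dataset the
rejected transcripts concentrate on map units whose true-label mixture
is maximally mixed, i.e. on the boundary between the coding and
non-coding regions of the map.

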