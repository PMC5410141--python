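# ptmsvm

Multiple-kernel SVM prediction of protein post-translational-modification
(PTM) sites.

## The problem

Phosphorylation, O-GlcNAcylation, sulfation, nitration and related PTMs
occur on serine, threonine and tyrosine residues, and experimentally
mapping them is slow and expensive. Two regularities make the problem
learnable: modified sites sit inside conserved local sequence motifs,
and sites carrying one modification are more likely to carry related
ones. `ptmsvm` combines both sources of evidence in a single classifier
for computational biologists who want ranked candidate sites for a
target PTM or kinase group.

## The method

Each candidate site is a 21-residue peptide window *t* (10 residues
either side of the central S/T/Y). Two kernels over sites are built:

* **Local sequence kernel.** Raw similarity is the positionwise
  BLOSUM62 sum
  `S_seq(t_i, t_j) = Σ_{x=1..21} BLOSUM62(t_i(x), t_j(x))`,
  min-max normalized to `K_seq ∈ [0, 1]`.
* **Gaussian interaction-profile (GIP) kernel.** From the bipartite
  site–modification network with binary adjacency *A* (row `A_i` is the
  interaction profile of site *i*),
  `K_GIP(t_i, t_j) = exp(−γ ‖A_i − A_j‖²)` with bandwidth γ = 0.001.

The combined kernel `K = Σ_d β_d K_d` (β_d ≥ 0, default ½/½) is passed
to a soft-margin SVM as a precomputed Gram matrix, with per-class
penalties `C_± = C·N/(2N_±)` to balance unequal class sizes.
Probabilities come from Platt scaling on out-of-fold decision values.

Evaluation is stratified ten-fold cross-validation repeated ten times.
Inside every fold the target-PTM column of the held-out sites is zeroed
and the GIP kernel recomputed, and the sequence-kernel normalization
constants are taken from the training block only — so no information
about held-out labels can reach the model. Reported metrics are Sn, Sp,
Pre, Acc, MCC, ROC/AUC, sensitivities at specificity-anchored
thresholds (Sp ≥ 95% / 99%), and top-p% retrieved fractions.

A synthetic-data module generates motif-bearing positive windows,
background negatives and correlated site–modification networks with
controllable signal strength, so the whole pipeline is testable without
any external database.

## Worked example

```
ptmsvm simulate --out data --seed 7 --n-pos 40 --n-neg 40
ptmsvm cv --fasta data/proteins.fasta --sites data/sites.tsv \
          --adjacency data/adjacency.tsv --seed 7 --folds 5 --repeats 2 \
          --out cvout
python -c "import json; d=json.load(open('cvout/metrics.json'))['averaged']; \
           print({k: d[k] for k in ('auc','sn','sp','mcc')})"
```

prints

```
{'auc': 1.0, 'sn': 1.0, 'sp': 1.0, 'mcc': 1.0}
```

The simulated dataset has a strong sequence motif (90% consensus match)
and strong annotation co-occurrence (60% vs 5% background), so the
combined kernel separates the 40 positive from the 40 negative sites
perfectly in cross-validation: AUC, sensitivity, specificity and
Matthews correlation are all 1.0. Weakening the signal
(`--match-prob 0.2 --co-occurrence-prob 0.1`) drops the AUC toward
chance. `ptmsvm train` then fits a final probability-calibrated model
on all labeled sites and `ptmsvm predict` writes a candidate table
ranked by predicted modification probability, the output an
experimentalist would triage.

The same workflow is available as a library: `generate_dataset`,
`run_cv`, `fit_predictor`, `rank_candidates` (see docstrings), and
`signal_sweep` reproduces the AUC-vs-signal-strength comparison of the
three kernel configurations in one call.

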