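# ntenet

Directed functional brain networks from normalized transfer entropy (NTE),
with a synthetic EEG cohort generator, graph-theoretic network
characterization, hemisphere/region information-flow statistics, and
novice/expert classification — the analysis stack used to compare how
trained and untrained users of a 3D-modelling tool route information
between brain regions while resting, drawing, and manipulating objects.

## Who this is for

Researchers studying effective (directed) connectivity in multichannel
EEG with consumer-grade 14-channel headsets (AF3, F7, F3, FC5, T7, P7,
O1, O2, P8, T8, FC6, F4, F8, AF4), and anyone who needs a tested,
reproducible reference implementation of surrogate-corrected transfer
entropy networks and their graph measures.

## The measure

Signals are reduced to symbols by equiprobable amplitude binning. Transfer
entropy from source *y* to target *x* (embedding dimension 1, lag 1) is

```
TE(y→x) = Σ p(x_{n+1}, x_n, y_n) · log₂[ p(x_{n+1}, x_n, y_n) p(x_n)
                                         / (p(x_n, y_n) p(x_{n+1}, x_n)) ]
```

Finite data bias is removed with shuffled-source surrogates and the result
is expressed as a fraction of the target's own information budget:

```
NTE(y→x) = (TE(y→x) − ⟨TE(y_shuffle→x)⟩) / H(x_{n+1} | x_n)  ∈ [0, 1]
```

The 14×14 NTE matrix is thresholded (default 0.001) into a binary
digraph for connectivity density, a 13-class census of 3-node motifs,
directed (Fagiolo) clustering, characteristic path length, and the
small-world index σ = (C/C_rand)/(L/L_rand) against 100 degree-preserving
random references; the weighted matrix feeds node strength
(Strengthᵢ = Σⱼ wᵢⱼ + Σⱼ wⱼᵢ) and hemisphere/region information-flow
summaries. Twenty-second task windows become 43-entry feature vectors
(density, 13 motif counts, 14 clustering coefficients, path length, 14
per-electrode outflows) classified by LDA / k-NN / naive Bayes / SVM /
decision tree with greedy sequential forward selection under stratified
5-fold cross-validation.

No public recordings accompany the original study, so the package ships a
generator of 14-channel cohorts driven by a tanh-coupled autoregressive
network whose ground-truth directed coupling is stored beside every
recording; novice profiles engage progressively harder from rest through
drawing to manipulation, expert profiles plateau once the task starts.

## Worked example

```python
import numpy as np
from ntenet import (make_cohort, filter_recording, epoch_by_state,
                    nte_matrix, binarize, small_world_index,
                    mean_information_flow)

rec, profile, coupling = make_cohort(n_novice=1, n_expert=0, seed=7)[0]
rec = filter_recording(rec)                      # 45 Hz LP, 0.1 Hz HP, notches
m = nte_matrix(epoch_by_state(rec, "drawing"))   # 2-s epochs, averaged
print(profile.expertise, m.n_epochs_averaged)
print(round(float(m.values.max()), 3))
g = binarize(m)                                  # threshold 0.001
sw = small_world_index(g, n_random=100, seed=7)
print(round(sw.sigma, 3), g.n_edges)
print(round(float(mean_information_flow(m).mean()), 4))
```

prints

```
novice 25
0.028
1.0 182
0.1069
```

meaning: 25 clean two-second epochs were averaged, the strongest directed
link carries ~3% of its target's information budget, the thresholded
network keeps all 182 possible edges (the 0.001 threshold removes only
negligible links, so density-based contrasts live in the weighted
measures), its small-world index is ≈1 (a dense graph is its own random
null), and each electrode sends ≈0.1 bits-per-bit of summed normalized
outflow in the drawing state.

The same pipeline end-to-end, from a shell:

```
ntenet run-all --seed 7 --out runs/demo
```

writes raw/preprocessed CSV recordings, per-state NTE matrices (TSV),
GraphML networks with a tidy metrics table, statistics tables (ANOVA with
Tukey–Kramer comparisons, Welch state contrasts, region flows), and a
classification report, each stamped with the producing config hash.

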