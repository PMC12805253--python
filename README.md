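# cnattention

Pan-cancer classification and **copy-number aberration (CNA) signature
discovery** with attention-based multiple-instance learning, for researchers
working with gene-level, GISTIC-style discrete copy-number calls
(−2 deep loss, −1 shallow loss, 0 diploid, +1 gain, +2 amplification — the
format distributed by cBioPortal).

CNA profiles of one cancer type vary strongly between patients. The package
therefore treats classification as a multiple-instance problem: an *instance*
is a single patient profile x_k, a *bag* is a set of K instances sharing one
cancer-type label. Instances are embedded by a neural map h_k = f_ψ(x_k),
pooled with **gated attention**

    a_k = softmax_k( wᵀ[ tanh(V h_k) ⊙ σ(U h_k) ] ),   z = Σ_k a_k h_k,

and the bag embedding z is classified by g_φ with a softmax head; training
minimizes the multinomial bag negative log-likelihood −log p[label]. The
attention weights identify *key instances* — the most typical CNA patterns of
a class — and are recycled after training: each instance's
attention-normalized class score p̂_{i,k} = (w_i/Σ_j w_j)·p_{i,k} is projected
onto genes, s_{g,k} = mean_{i: ĉ_i=k} p̂_{i,k}·x_{i,g}, yielding per-type
signatures of signed gene scores (positive = duplication-associated,
negative = deletion-associated).

Around this core the package provides cross-validated recursive feature
elimination (RFECV) over genes, a simulator of multi-class cohorts with
planted aberration blocks and subtypes, and comparison metrics
(gain/loss frequency profiles, chromosome-arm aggregation, Spearman arm
concordance, gene-set Jaccard). See `docs/methods.md` for the full model
description, defaults and limitations.

## Worked example

```python
import cnattention as cn

# a simulated 3-class cohort: 40 samples/class, 500 genes, two planted
# 10-gene blocks per class (one gain, one loss), penetrance 0.95
cohort, truth = cn.simulate_cohort(
    cn.SimulationConfig(penetrance=0.95, background_rate=0.01, seed=3))
train, test = cn.split_cohort(cohort, 0.2, seed=5)

model = cn.CNAttention(train, embed_dim=64, attention_dim=32)
res = model.fit(cn.TrainConfig(epochs=50, seed=0))
print(res.summary(test))
```

```
      Attention-MIL copy-number classifier
====================================================
classes:            3
genes (features):   500
embedding width M:  64
attention width L:  32
bag size K:         10
epochs run:         50
final train loss:   0.0000
best val bag acc:   1.0000
bag accuracy:       1.0000
instance accuracy:  0.9583
====================================================
```

Held-out bags are classified perfectly; instance accuracy is 0.96 — the
missing 4% are samples that carry none of their class's planted blocks
(5% expected at penetrance 0.95) and are irreducibly ambiguous. The
signatures recover the planted blocks with correct directions:

```python
sigs = res.signatures(n_per_class=5, seed=0)
print(sigs.to_frame().head(5).to_string(index=False))
```

```
 class   gene     score direction  rank
type01 g00006  1.000000       dup     1
type01 g00016 -0.892861       del     2
type01 g00018 -0.886689       del     3
type01 g00001  0.853731       dup     4
type01 g00007  0.813316       dup     5
```

type01's planted gain block is genes g00000–g00009 and its loss block
g00010–g00019: the top-scoring genes are exactly planted genes, gains as
`dup`, losses as `del`.

The same pipeline is scriptable from the shell:

```bash
cnattention simulate --seed 3 --out-dir sim/
cnattention run --config pipeline.yaml      # split → RFECV → train → evaluate → signatures
cnattention compare freq --matrix sim/matrix.tsv --out freq.tsv
```

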