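# lpipredict

Prediction of lncRNA–protein interactions by integrating a restart
random walk on the lncRNA similarity graph with neighborhood-regularized
logistic matrix factorization (NRLMF).

Long non-coding RNAs mostly act through the RNA-binding proteins they
associate with, but experimentally mapping those associations is slow
and costly, and there is no reliable set of verified *non*-interactions
to train a conventional classifier on. This package implements a
semi-supervised approach that needs only the known interactions plus
sequence-derived similarity on each side. It is aimed at computational
biologists who have (or can compute) an interaction edge list and
FASTA sequences, and want ranked candidate pairs plus a rigorous
cross-validated estimate of ranking quality.

## Method

Given the binary interaction matrix **Y** (m lncRNAs × n proteins) and
normalized Smith–Waterman similarity matrices **LS** (m×m) and **PS**
(n×n), with `S(a,b) = sw(a,b) / max(sw(a,a), sw(b,b))`:

1. **Random walk, per protein.** LncRNAs interacting with protein *p*
   seed a restart walk on the similarity-weighted lncRNA graph:

       S(t+1) = r_Q·L_Qᵀ·S(t) + p_Q(1−r_Q)·X + r_U·L_Uᵀ·S(t) + p_U(1−r_U)·X

   where L_Q/L_U are the labeled/unlabeled rows of the row-normalized
   transition matrix, X is the uniform seed distribution, and
   p_Q = Σ_{i∈Q} S_i(t). The steady state is the score column S_R(·, p).

2. **NRLMF.** Interaction probability σ(u_i·v_j) with latent factors
   fit by AdaGrad on a c-weighted logistic likelihood plus Gaussian
   priors and graph-Laplacian neighborhood regularization; entities with
   no training links are scored through similarity-weighted neighbor
   smoothing. This gives S_N.

3. **Integration.** S = (S_R + S_N)/2, optionally after putting both on
   a common per-column [0, 1] scale.

4. **Evaluation.** Leave-one-out cross-validation over the known
   interactions, with AUC, AUPR and thresholded ACC/SEN/PRE/F1.

See `docs/methods.md` for assumptions, parameter meanings and defaults,
numerical conventions, and what the synthetic benchmark does and does
not demonstrate.

## Worked example

```python
from lpipredict import (SyntheticSpec, simulate_dataset, score_matrix_rw,
                        integrate, loocv, roc_auc, aupr, top_pairs)
from lpipredict.nrlmf import score_matrix_nrlmf

ds, lnc_sim, prot_sim, truth = simulate_dataset(SyntheticSpec(seed=2))
print(f"{ds.shape[0]} lncRNAs x {ds.shape[1]} proteins, "
      f"{ds.n_interactions} known interactions")

S_R = score_matrix_rw(ds, lnc_sim)               # restart-walk scores
S_N = score_matrix_nrlmf(ds, lnc_sim, prot_sim)  # factorization scores
S = integrate(S_R, S_N)                          # final prediction
print(top_pairs(S, k=3, exclude=ds.Y).to_string(index=False))

res = loocv(ds, lnc_sim, prot_sim, arm="integrated", normalize=True)
print(f"LOOCV AUC = {roc_auc(res):.4f}, AUPR = {aupr(res):.4f}")
```

Output:

```
60 lncRNAs x 12 proteins, 124 known interactions
 lncrna protein    score  rank
lnc0037 prot005 0.471597     1
lnc0036 prot005 0.460035     2
lnc0006 prot002 0.455864     3
LOOCV AUC = 0.8849, AUPR = 0.6414
```

The top-pairs table ranks *novel* candidates (known interactions are
excluded); scores average a walk probability and a logistic probability,
so they order pairs rather than estimate calibrated probabilities. The
LOOCV AUC says a withheld true interaction outranks a random unknown
pair ~88% of the time on this synthetic dataset.

The same workflow is available from the shell:

```sh
lpipredict simulate --out fixture --seed 2
lpipredict predict --interactions fixture/interactions.tsv \
    --lnc-sim fixture/lnc_sim.tsv --prot-sim fixture/prot_sim.tsv \
    --arm integrated --out pred
lpipredict loocv --interactions fixture/interactions.tsv \
    --lnc-sim fixture/lnc_sim.tsv --prot-sim fixture/prot_sim.tsv \
    --arm rw --arm nrlmf --arm integrated --out cv
```

`lpipredict similarity` builds the similarity matrices from FASTA for
real data, and `lpipredict gridsearch` tunes the factorization
hyperparameters by cross-validated AUC.

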