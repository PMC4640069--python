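# metacomm

Metacommunity typing, dysbiosis scoring and compositional correlation
networks for mucosal microbiome cohorts.

Mucosal biopsies from tumour-bearing colons show recurring community
configurations — *metacommunities* — whose identity shifts along the
normal → adenoma → carcinoma sequence, together with changes in
taxon–taxon co-occurrence structure. `metacomm` implements the analysis
pipeline for paired lesion / lesion-adjacent 16S phylotype count tables:

- **Dirichlet multinomial mixture (DMM) typing.** Each sample's counts
  `x_j` follow a multinomial whose proportions are drawn from one of K
  component Dirichlets: `x_j | z_j=k ~ DirMult(alpha_k)`. Mixtures are
  fitted by EM (quasi-Newton M-step on `log alpha`), and K is chosen by
  a Laplace approximation to the log model evidence,
  `log p(X) ~ log p(X, theta*) + (P/2) log 2*pi - (1/2) log |H|`,
  with medoid-based cross-checks (PAM + Calinski–Harabasz on
  Bray–Curtis, NMDS + Procrustes) and a rarity-cutoff sweep.
- **Marker selection and MCPI.** Taxa with a >= 1.5 fold change of mean
  relative abundance vs normal controls, per contrast group C, C′, A,
  A′ (carcinoma / carcinoma-adjacent / adenoma / adenoma-adjacent). The
  Microbial Community Polarization Index of sample *j* is the composite
  of two dysbiosis log-ratios,
  `MCPI_j = log10(sum TI_C + eps / sum TD_C + eps) - log10(sum TI_A + eps / sum TD_A + eps)`,
  positive for carcinoma-characteristic shifts, negative for
  adenoma-characteristic ones.
- **Paired concordance analysis.** Transition tables of metacommunity
  labels from adjacent mucosae to lesions, per-stage stratification
  (LGDP/HGDP/ECRC/LCRC), Monte-Carlo Fisher association tests, and
  paired inverse-Simpson / MCPI comparisons.
- **SparCC correlation networks.** Basis correlations
  `rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j))` estimated from
  log-ratio variances `t_ij = var log(x_i/x_j)` under a sparsity
  assumption with iterative exclusion of strong pairs, permutation
  p-values, BH-FDR + strength filtering, and cross-state comparisons.
- **Synthetic cohorts.** A ground-truth generator emulating the paired
  study design (61 controls, 47 + 52 pairs, K = 5, variable depth,
  planted markers, tunable lesion/adjacent concordance), plus a
  known-basis compositional generator for calibrating the correlation
  machinery.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from sklearn.metrics import adjusted_rand_score
from metacomm import (default_paper_like_spec, generate_cohort, rarefy,
                      select_k, assign_metacommunity)

table, records, truth = generate_cohort(default_paper_like_spec(seed=1))
rarefied, _ = rarefy(table, 1000, seed=1)
selection = select_k(rarefied, range(1, 8), seed=1, n_restarts=1, tol=1e-5)
print(selection.best_K)
labels = [truth.component_labels[s] for s in rarefied.sample_ids]
print(round(adjusted_rand_score(labels, selection.best_model.hard_labels()), 3))
```

prints

```
5
1.0
```

i.e. on a 259-biopsy synthetic cohort generated from five
metacommunities, the Laplace evidence selects K = 5 and the posterior
assignment reproduces the generating labels exactly (adjusted Rand
index 1.0). The evidence curve behind this choice
(`selection.evidence`) rises to K = 5 and falls beyond it — the Occam
penalty of the Laplace approximation at work.

The `examples/` directory walks through each capability end to end
(simulation, typing, markers + MCPI, paired concordance, SparCC
networks) with printed output and one-line interpretations. A thin CLI
mirrors the pipeline for shell use:

```bash
metacomm simulate --seed 0 --out run/sim
metacomm partition --counts run/sim/counts.tsv --truth run/sim/truth.json --seed 0 --out run/part
metacomm analyze --counts run/sim/counts.tsv --metadata run/sim/metadata.tsv \
    --assignments run/part/assignments.tsv --seed 0 --out run/ana
```

## Documentation

`docs/methods.md` describes the models, the numerical choices
(EM tolerances, priors behind the evidence, Hessian structure,
exclusion heuristics), what the synthetic cohorts do and do not emulate,
and known limitations.
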