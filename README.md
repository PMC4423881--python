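# noisecorr

Noise-aware estimation of the genome-scale mRNA–protein correlation and of
the post-transcriptional amplification exponent from many noisy, partially
missing expression studies.

## The problem

Steady-state protein levels reflect mRNA levels modulated by translation
and degradation. How tightly the two are coupled is usually judged from the
observed correlation between log-transformed genome-scale mRNA and protein
measurements — but every such measurement carries substantial noise, and
most protein studies miss a large, *non-random* slice of the genome
(low-abundance proteins drop below detection limits). Both effects
systematically attenuate correlations and regression slopes toward zero,
so naive analyses understate the role of transcription and misestimate the
protein-per-mRNA scaling law.

`noisecorr` implements the estimators that undo these biases:

- **Reliability and attenuation corrections.** With measurements
  X = φ + ε, the reliability α = Var(φ)/Var(X) caps the observable
  correlation at √(α_X·α_Y). Given two replicates of each variable, the
  latent correlation is estimated as

      r̂ = (r_{x1y1} r_{x2y2} r_{x1y2} r_{x2y1})^{1/4} / √(r_{x1x2} r_{y1y2})

  with an N×M generalization using geometric means of all pairwise
  correlations.
- **Structured covariance model (SCM).** A Bayesian hierarchical model
  X_ij = L_{i,l[j]}·G_{l[j]} + T_{i,t[j]} + E_{i,k[j]} + R_ij + ν_j with
  latent per-gene (protein, mRNA) levels L_i ~ N₂(0, Ψ), stratified
  technology/experiment/replicate noise, and a logistic detection model
  P(observed | x) = expit(η⁰_k + η¹_k·x) for non-ignorable missingness.
  A Gibbs sampler returns the posterior of the latent correlation Ψ₁₂, the
  amplification exponent A = G_protein/G_mRNA (the log-log slope in
  P ≈ M^A), denoised per-gene levels, and per-study detection curves.
- **Model-II regression** (major-axis, standardized and ranged major-axis)
  for slope estimation when both variables carry error, immune to
  regression-dilution bias.
- **Synthetic-data generators** for all of the above, including a toy
  steady-state model in which translation rate rises as a power of mRNA
  level — showing that a near-perfect mRNA–protein correlation can coexist
  with strong post-transcriptional amplification.
- **Downstream summaries**: molecules-per-cell scaling, ribosome-density
  normalization, translational efficiency, ribosomes per mRNA species, and
  dynamic-range statistics.

## Worked example

```python
import numpy as np
import noisecorr as nc

sim = nc.simulate_noisy_replicates(
    nc.SimulationConfig(n_genes=5000, rho_true=0.9, reliability=0.7, seed=0))
m = sim.matrix
x1, x2 = m.column("mrna_1"), m.column("mrna_2")
y1, y2 = m.column("prot_1"), m.column("prot_2")

print(np.corrcoef(x1, y1)[0, 1])                            # 0.638
print(nc.reliability_from_replicates(x1, x2).alpha_hat)     # 0.702
print(nc.corrected_correlation_pair4(x1, x2, y1, y2).r_hat) # 0.894
```

The observed correlation (0.638) sits near ρ·α = 0.63 — noise hides a third
of the true association. The replicate correlation recovers the reliability
(0.702 ≈ 0.7), and the four-measurement correction recovers the latent
correlation (0.894 ≈ 0.9). The `examples/` directory has one short script
per capability (`spearman_correction.py`, `simulation_study.py`,
`toy_model.py`, `scm_fit.py`, `ribosome_summaries.py`); each prints the
numbers it computes and what they mean. For instance `examples/scm_fit.py`
fits the SCM to a simulated 8-study corpus with detection-biased
missingness and prints

```
latent mRNA-protein correlation: 0.916 +/- 0.012 (truth 0.9)
amplification exponent A       : 1.495 +/- 0.041 (truth 1.50)
detection is 50% at x ~ -0.50 for study 'protein_study1' (truth -0.50)
```

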