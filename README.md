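# isingbrain

Estimate how far a functional-connectivity network is from criticality, by
regressing the temperature of a 2D Ising model directly from the
connectivity matrix with a graph convolutional network (GCN).

Resting-state brain networks have been argued to operate near a
second-order phase transition, and the Ising model is the canonical minimal
model of such a transition: binary spins σ_i ∈ {−1, +1} on an L×L lattice
with Hamiltonian H = −J Σ_{<i,j>} σ_i σ_j, whose temperature T (in
k_B·T/J units) tunes the system between an ordered phase (T < T_c) and a
disordered one, with criticality at T_c = 2/ln(1+√2) ≈ 2.269. The package
is for researchers who want a scalable way to place subject connectivity
matrices on that order–disorder axis: instead of fitting a pairwise
maximum-entropy model per subject, a regressor is trained once on simulated
Ising connectivity and then applied to any number of subjects at negligible
cost.

The pipeline:

1. **Simulate** the Ising model by Metropolis–Hastings (L×L single-flip
   proposals per sweep, periodic boundaries), validated against Onsager's
   analytic magnetization m(T) = (1 − sinh(2/T)⁻⁴)^{1/8}.
2. **Coarse-grain** 200 equilibrium snapshots into block time series
   (13×13-spin blocks for L = 250), Pearson-correlate them, and
   centre-crop the 361×361 correlation matrix to 333×333 — the
   dimensionality of a 333-parcel cortical connectivity matrix.
3. **Train** a GCN (three symmetric-normalised graph convolutions, global
   average pooling, two linear layers; MAE loss with L2 penalty, triangular
   cyclical learning rate) on kNN graphs labelled with their generating
   temperature, drawn uniformly from [1.8, 2.5].
4. **Estimate** T̂ for subject connectivity matrices or ROI time series and
   report T̂ − T_c.
5. **Analyse** a cohort: Pearson/Spearman age trends, 2-year age-bin
   |T̂ − T_c| tables with Welch t tests, BCa bootstrap comparison of group
   correlations, and a motion/age confound regression.

A synthetic-cohort generator produces phenotype tables and Ising-derived
connectivity whose true temperature declines linearly with age, so the
entire chain is testable end to end without any external imaging data.

## Worked example

```python
import isingbrain as ib

# 1. the simulator thermalises onto the analytic curve
m = ib.simulate(ib.SimulationConfig(L=64, T=2.0, burn_in=500,
                                    n_record=200, seed=7)).mean_abs_magnetization()
print(f"mean |m| at T=2.0: {m:.4f}  (Onsager: {ib.onsager_magnetization(2.0):.4f})")
print(f"critical temperature: {ib.critical_temperature():.4f}")
```

```
mean |m| at T=2.0: 0.9089  (Onsager: 0.9113)
critical temperature: 2.2692
```

The recorded magnetization sits within 0.003 of the infinite-lattice value
— the simulator is in equilibrium. Training and applying the regressor at
desk scale (the `small` preset: L = 114 with 6-spin blocks gives the same
361 → 333 geometry as L = 250 with 13-spin blocks):

```bash
isingbrain build-dataset --n 300 --preset small --splits 200,50,50 --seed 11 --out ds/
isingbrain train --dataset ds/ --out model.npz
# best val MAE 0.0981; test MAE 0.0989, R2 0.4578
isingbrain connectivity --L 114 --block 6 --target 333 --T 2.0 --burn-in 500 --seed 99 --out subj.csv
isingbrain estimate --model model.npz --input subj.csv --subject-id demo
```

A held-out MAE of ≈ 0.1 over the 0.7-wide training interval means the
desk-scale model resolves roughly seven temperature levels — enough to
recover cohort-level trends (the test suite demonstrates a significant
negative age–T̂ correlation on a synthetic cohort with a −0.02/year drift
at n = 150). Full-scale accuracy (MAE ≈ 0.04, R² ≈ 0.92) needs the `full`
preset — 1,500 simulations at L = 250 and several CPU-hours; the commands
are identical with `--preset full`. See `docs/methods.md` for why the
desk-scale error concentrates above T_c.

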