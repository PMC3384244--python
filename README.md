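# stresscircuit

Modeling a **self-limiting recombinant protein production circuit** in
*Escherichia coli*: IPTG induces T7 RNA polymerase, T7 polymerase drives
high-level GFP expression, and the resulting misfolded-protein stress
activates an IbpAB-type stress promoter expressing a degradation-tagged TetR
repressor that closes a **negative feedback loop** onto the GFP gene.  The
feedback trades total protein yield for protein quality: strong feedback
cuts peak GFP by roughly 70% relative to the unregulated control while
increasing the soluble (non-inclusion-body) fraction of the product.

The package is aimed at systems/synthetic biologists who want to simulate,
calibrate and stress-test this class of circuit against plate-reader data:

- **Circuit model** (`stresscircuit.model`) — eight species
  (mRNA/protein for T7 polymerase, GFP and TetR, plus the GFP folding
  intermediate, native and inclusion-body pools) with Hill
  activation/repression kinetics, explicit transcription/translation delays
  and growth dilution.  For the GFP channel, with delayed arguments written
  as x(t−τ):

  ```
  dm_G/dt = k_tx_G · p_T7(t−τ_tx) / (1 + (p_R(t−τ_tx)/K_tetR)^n) − (d_m+μ)·m_G
  dg_F/dt = k_tl_G · m_G(t−τ_tl) − fold(g_F) − k_agg·g_F − (d_G+μ)·g_F
  dg_N/dt = fold(g_F) − (d_G+μ)·g_N          fold(g) = k_fold·g / (1 + g/K_fold_sat)
  dg_I/dt = k_agg·g_F − (k_ib_deg+μ)·g_I
  ```

  where the saturable `fold` term models finite chaperone capacity and the
  stress promoter driving TetR senses the misfolded load `g_F + g_I`.
- **DDE engine** (`stresscircuit.dde`) — method-of-steps integration on
  `scipy.integrate.solve_ivp` with stored dense-output history, pre-induction
  steady-state burn-in, and an independent fixed-step Euler oracle for
  verification.
- **Calibration** (`stresscircuit.calibrate`) — fluorescence↔concentration
  conversion, multi-start least-squares fitting of any parameter subset to
  replicate time courses (log-scale residuals, optional end-point
  soluble-fraction terms), local sensitivity ranking, and grouped
  cross-validation.
- **Synthetic data** (`stresscircuit.synth`) — ground-truth-known
  plate-reader datasets: exponential OD600 growth, per-clone lognormal
  variability, multiplicative measurement noise, and 8-h soluble/insoluble
  fractionation tables.
- **Reporting + CLI** (`stresscircuit.reporting`, `stresscircuit.cli`) —
  variant comparison tables and a config-driven pipeline
  (`stresscircuit pipeline --config examples/demo_config.yaml`).

## Worked example

```python
from stresscircuit import CircuitParameters, InductionSchedule, STANDARD_VARIANTS, simulate
from stresscircuit.reporting import compare_variants

params = CircuitParameters()                      # calibrated fixture
schedule = InductionSchedule(iptg_conc=1.0, t_induce=2.0, t_end=12.0)
trajs = {lab: simulate(params, v, schedule) for lab, v in STANDARD_VARIANTS.items()}
print(compare_variants(trajs).table[
    ["variant", "total_gfp_end", "soluble_fraction_8h", "max_reduction_total_pct"]
])
```

prints (see `examples/01_simulate_variants.py`):

```
   variant  total_gfp_end  soluble_fraction_8h  max_reduction_total_pct
MUT_STRONG       5118.871                0.494                   46.948
  MUT_WEAK       8296.768                0.476                   14.012
     NO_FB       9648.728                0.472                    0.000
 WT_STRONG       3057.460                0.526                   71.049
```

Reading this: end-point total GFP falls monotonically with feedback
strength (no feedback → mutant promoter/weak RBS → mutant/strong →
wild-type/strong), the strong feedback reaches a maximal post-induction
reduction of ~71% versus the control, and the 8-h soluble fraction rises
from 0.47 to 0.53 — the yield/quality trade-off the circuit is built
around.  The other scripts in `examples/` walk through synthetic-data
generation, parameter recovery with cross-validation, and sensitivity
ranking.

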