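# promcycle

Stochastic promoter-cycle analysis of transcriptional bursting in mammalian
cells: exact likelihoods for single-allele luminescence time traces,
reversible-jump MCMC identification of the number and durations of
rate-limiting silent promoter steps, trajectory deconvolution, and mRNA
noise decomposition — including recovery-corrected noise analysis of UMI
single-cell RNA-seq counts.

## The problem

Mammalian genes transcribe in bursts: short active periods separated by long
silent intervals.  When silent-interval durations are *peaked* rather than
exponential, reactivation has a refractory period, implying several
sequential rate-limiting steps.  `promcycle` models a single gene copy as an
irreversible cycle of one active state and `N` sequential inactive states
with escape rates `k_1 … k_N`, coupled to birth–death kinetics of mRNA
(transcription `k_m` while active, decay `γ_m`) and protein (`k_p`, `γ_p`).
The silent period `T = Σ 1/k_i` is then phase-type distributed —
exponential for `N = 1`, Gamma-like (peaked) for several equal steps.

From noisy, sampled protein-reporter signals the package infers the
posterior over `N` and the kinetic rates via RJ-MCMC on the exact
master-equation likelihood, reconstructs hidden promoter-activity and mRNA
trajectories by forward-filtering backward-sampling, and quantifies how the
cycle shapes mRNA noise:

    η² = η_p² + η_c²,   η_p² = 1/⟨m⟩,   η_c² = f·C,
    f = (τ_a + T)/τ_m,  C ∈ [1/2, 1] when bursting (τ_a ≪ T),

with `C = 1` for a single silent step and `C(N) = (1 + 1/N)/2` for `N` equal
steps in the bursting limit — so multi-step cycles buffer promoter noise by
up to a factor of two, and promoter noise exceeds Poisson noise whenever the
burst size `b = k_m τ_a` exceeds 2.  The same algebra, applied through
cell-specific binomial recovery of UMI counts, predicts and measures the
excess intrinsic noise of single-step (TATA-like) promoters in single-cell
RNA-seq.

## Worked example

```python
import numpy as np
from promcycle import (PromoterCycleModel, CalibrationModel, generate_cohort,
                       deconvolve_dataset, split_total_noise,
                       model_intrinsic_noise)

# six equal 15-min silent steps, 8-min active periods, 5 mRNA/min while on
model = PromoterCycleModel.equal_steps(6, 90.0, off_rate=1/8, k_m=5.0,
                                       k_p=1.0, gamma_m=1/20, gamma_p=1/30)
nz = model_intrinsic_noise(model)
print(f"f={nz['f']:.2f}  C={nz['C']:.3f}  eta2={nz['eta2']:.3f}")
```

prints

```
f=4.90  C=0.528  eta2=2.712
```

the normalized cycle duration `f`, the promoter coefficient `C` (between the
bursting bounds 1/2 and 1), and the stationary intrinsic mRNA noise — which
a long Gillespie simulation of the same model reproduces within Monte-Carlo
error (`tests/test_noise.py`).  The numbered drivers under `analysis/` walk
through the full pipeline on synthetic cohorts and write their tables under
`results/`:

1. `01_simulate_cohorts.py` — one-step vs six-step cohorts; off-interval CV
   0.97 vs 0.41 (exponential vs Gamma(6) ≈ 0.41).
2. `02_infer_promoter_cycle.py` — scaled-down RJ-MCMC recovery of `N`,
   `k_m`, `τ_a`, `T` from a synthetic cohort.
3. `03_deconvolve_traces.py` — activity/mRNA reconstruction; pooled
   posterior mRNA histogram within TV 0.01 of the exact stationary law.
4. `04_noise_decomposition.py` — the C(N) curve and the intrinsic/extrinsic
   split on a heterogeneous cohort.
5. `05_umi_noise.py` — synthetic UMI cohorts; predicted TATA-class excess
   noise 0.027, measured 0.027, split control corrects to ~0.

A `promcycle` command-line tool exposes the same stages
(`simulate`, `infer`, `deconvolve`, `noise`, `umi-noise`, `validate`).

## Layout

```
src/promcycle/      model, simulate, likelihood, rjmcmc, deconvolve,
                    noise, scnoise, io, pipeline, cli
analysis/           numbered narrative drivers (write to results/)
scripts/            acceptance.py
docs/methods.md     model assumptions, priors, numerical choices, caveats
tests/              pytest suite (oracle-based: enumeration, quadrature,
                    closed forms, long-run simulation)
```
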