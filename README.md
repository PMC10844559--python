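# viscofit

Surrogate-accelerated inverse viscoelastic characterization of ultrasoft
materials (brain-tissue-like), at material-point desk scale.

Identifying constitutive parameters for ultrasoft tissues requires inverse
fitting: a forward model replays the experiment (here: cyclic
compression–tension, stress-relaxation holds, and torsional shear on a
cylindrical specimen) and an optimizer adjusts the parameters until the
simulated stresses match the measured ones.  When every forward evaluation
is expensive, a learned surrogate can stand in for most of them.  This
package implements that pipeline end to end:

* **Forward model** — a finite-strain generalized Maxwell solid (equilibrium
  one-term Ogden spring + one Ogden/dashpot Maxwell branch, multiplicative
  split F = FᵉFᵛ, purely deviatoric viscous flow, exponential-map
  integrator) driven by an axial-stretch/shear protocol with a
  traction-free lateral surface.  Parameters: μ∞, α∞, μ₁, α₁, η₁ at fixed
  Poisson ratio ν = 0.45, with κ = 2μ(1+ν)/(3(1−2ν)) per spring.
* **Synthetic experiments** — rheometer records (P = f_z/A, τ = 2t/πr³)
  with seeded noise, moving-average and Ramer–Douglas–Peucker filtering.
* **LSTM surrogate** — a sequence-to-sequence network
  (LSTM 64 → dropout → LSTM 64 → dropout → dense 2) mapping parameters +
  strain history to the stress channels, trained with MAE/Adam on
  z-score-normalized data; implemented directly in NumPy with
  finite-difference-verified backpropagation.
* **Active learning** — Monte-Carlo-dropout variance acquisition with a
  normalized-distance diversity constraint, growing the training pool from
  a Poisson-disk seed; plus a random-sampling baseline.
* **Identification** — normalized-L2 misfit χ² = Σ(y_exp−y_sim)²/Σy_exp²
  per channel, bounded trust-region-reflective least squares, and a hybrid
  driver that fits the surrogate first and restarts from its optimum with
  the high-fidelity model.

See `docs/methods.md` for the model equations, numerical choices, and the
desk-scale problem sizes.

## Worked example

Simulate the forward response of the default 30 s protocol (two
compression–tension cycles, two relaxation holds, two shear cycles; 300
samples) for a brain-tissue-like parameter set:

```sh
cat > params.json <<'JSON'
{"mu_inf": 162.0, "alpha_inf": -16.0, "mu_1": 398.0, "alpha_1": -18.0, "eta_1": 13949.0}
JSON
viscofit simulate --params params.json --out response.csv
# wrote response.csv (300 samples)
```

The output CSV has columns `time,stretch,shear,P,tau` (SI units).  For
this parameter set the nominal stress spans −362.8 … 147.1 Pa — the strong
compression–tension asymmetry of the negative Ogden exponents — and the
shear stress ±62 Pa.

The other subcommands drive the rest of the pipeline:

```sh
viscofit generate-data --params params.json --noise-level 0.01 --seed 3 --out record.csv
viscofit learn --config run.json --mode active --out run/     # pool + checkpoint + history
viscofit evaluate --checkpoint run/checkpoint --n-test 100 --seed 1
viscofit identify --record record.csv --checkpoint run/checkpoint \
                  --out best.json --trace-out trace.csv
```

`identify` reports the best-fit parameters, per-channel χ², and the number
of model evaluations per phase (surrogate / high-fidelity) — the quantity
that determines how many forward simulations the surrogate saved.

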