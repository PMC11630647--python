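# fedbatch

Kinetic modeling, statistical term selection, and optimal control of
fed-batch bioprocesses — a define / fit / optimize workflow for process
engineers who have a handful of non-optimal training fermentations and want
a data-driven optimal feed and temperature profile.

The package targets recombinant-protein fed-batch production (the built-in
defaults emulate an intracellular product expressed by *E. coli* on a
defined medium), but the model family is generic:

* **define** — a four-state ODE process model (biomass X, intracellular
  product P, substrate G, volume V) in which the cell-specific substrate
  uptake γ∘ splits additively into growth, production and maintenance
  channels (γ∘ = γμ + γπ + γα).  Uptake and production follow
  Michaelis–Menten kinetics with optional non-competitive inhibition by
  substrate, generations since induction, product load P/X and biomass;
  maintenance carries optional linear activation terms; each rate's scale
  is optionally a 4-parameter transition-state temperature law with
  logistic heat inactivation.  The general model has 29 parameters, 27 of
  them fitted (the two yields come from metabolic modeling).
* **fit** — spline-based estimation of observed specific rates from
  measured trajectories (the differential method), global parameter
  fitting per rate equation with seeded differential evolution, and
  backward elimination of insignificant terms with per-term F-tests; the
  significance level is chosen by leave-one-run-out cross-validation of
  the predicted final product-to-biomass yield Y_PX, with an exhaustive
  AICc-based selection as an alternative.
* **optimize** — transcription of the fitted model into a nonlinear
  program by orthogonal collocation on finite elements (implicit midpoint
  for the smooth states, backward Euler for the stiff substrate) and
  maximization of Y_PX = P(t_end)/X(t_end) over the feed-rate and
  temperature profiles, with a control-smoothness penalty and the process
  constraints (volume limit, sampling withdrawals, control bounds).
  A response-surface (quadratic CCD) baseline is included for comparison,
  plus a synthetic-data generator so the whole pipeline is testable
  end-to-end against a known ground truth.

## Worked example

```python
from fedbatch.synthetic import make_truth_params, generate_dataset, NoiseSpec
from fedbatch.rate_estimation import estimate_rates
from fedbatch.model_fitting import eliminate_terms, assemble_parameter_set
from fedbatch.optimal_control import (OCPConstraints, CollocationConfig,
                                      optimize_process)
from fedbatch.synthetic import quasi_steady_substrate

truth = make_truth_params()                   # documented 12-parameter truth
runs = generate_dataset(truth, noise=NoiseSpec(0, 0, 0), seed=3)
obs = estimate_rates(runs, (truth.Y_XrG, truth.Y_PG),
                     smoothing={"X": 0, "P": 0, "G": 0})

fits = {}
for rate in ("uptake", "maintenance", "production"):
    mask, fit, trace = eliminate_terms(obs, rate, alpha=0.2, seed=1)
    fits[rate] = fit
model = assemble_parameter_set(fits, truth.Y_XrG, truth.Y_PG)

f0 = 0.12 * 30.0 * 1.3 / model.Y_XrG
cons = OCPConstraints(G0=quasi_steady_substrate(model, f0 / 39.0))
res = optimize_process(model, CollocationConfig(n_elements=24), cons)
print(f"optimal YPX = {res.yield_term:.4f} (re-simulated {res.resim_ypx:.4f})")
print(f"optimal temperature ~ {res.profile.T_values.mean():.1f} C")
```

Output:

```
optimal YPX = 0.2137 (re-simulated 0.2131)
optimal temperature ~ 33.7 C
```

Read: fitted from twelve simulated training runs (centered at 31 °C,
exponential feeds, the center point ending at a yield of 0.173 g product
per g biomass), the optimizer finds that raising the temperature to
~33.7 °C — where the fitted production law peaks — and feeding along a
nearly linear, rising profile lifts the final product-to-biomass yield to
~0.214 g/g, a ~23% improvement over the training center point.  The
collocated and re-simulated yields agree to well under 1%, confirming the
transcription.

The same workflow is available from the shell:

```bash
fedbatch synth --out data/ --seed 0
fedbatch fit --dataset data/ --out fitdir/ --alpha 0.2 --seed 0
fedbatch optimize --params fitdir/fitted_params.yaml --out optdir/
fedbatch rsm --dataset data/ --out rsmdir/
```

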