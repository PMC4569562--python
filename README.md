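# divwaves

Collapse-driven population dynamics in saturated environments.

## The problem

Many communities — bacterial strains sharing a nutrient pool and culled by
strain-specific phages, taxa wiped out by epidemics or catastrophes, even
firms sharing a market — live at the carrying capacity of their
environment: one population can only grow if others shrink.  Classic
neutral models redistribute that capacity by incremental birth–death
drift.  `divwaves` simulates the opposite regime, where redistribution is
driven entirely by **abrupt whole-population collapses**: at each discrete
time step one species is wiped out (its probability of collapse
independent of its size in the basic model), a new species is seeded at a
tiny fraction γ of the capacity, and the freed resources are instantly
redistributed among the survivors by exponential regrowth.

With the total capacity normalised to 1 and N species slots, the dynamics
between collapses is the competitive logistic system

    dP_i/dt = Ω_i · P_i · (1 − Σ_j P_j),

and a collapse sets one P_i to γ (or to γ_i·P_i in the "resilience"
variant).  Because regrowth is fast compared to collapses, the simulator
jumps straight to the saturated endpoint of each regrowth phase.

Despite having a single parameter pair (N, γ), the model produces rich
emergent behaviour, which the analysis layer measures:

* **diversity waves** — the inverse-Simpson diversity D = 1/ΣP²
  jumps when a dominant species (P > 1 − 1/N) collapses and then decays
  ≈ exp(−t/N); waves last ~ N·ln N collapse steps;
* a **bimodal time-aggregated abundance distribution**
  π(P) = dProb(P_i > P)/d log₁₀P, whose upper tail follows a power law
  dProb/dP ∝ P^−τ with a universal exponent **τ ≈ 1.7** for γ ≪ 1/N
  (τ = 2 exactly if all abundances are equalised at each wave start);
* **cross-wave memory** — the hierarchical sub-peak structure of survivor
  jumps −ln(1 − P_collapsed), which grows as exp(t/N)/N within a wave.

Seven published variants are included: neutral drift between collapses,
multiplicative ("exponential") fluctuations, interconnected environments,
Kill-the-Winner (collapse probability ∝ P^σ), Kill-the-Loser (∝ P^−0.2),
heterogeneous fitness (per-species growth rate Ω_i and collapse weight
c_i), and resilience (per-species survivor ratio γ_i, no extinction).

## Worked example

```python
import numpy as np
from divwaves import ModelParams, simulate
from divwaves.recorders import SADRecorder, WaveRecorder, DiversityRecorder
from divwaves.analysis import WaveStats, fit_powerlaw_tail, wave_statistics

params = ModelParams(N=200, gamma=1e-9, seed=42)
sad, waves, div = SADRecorder(), WaveRecorder(), DiversityRecorder()
simulate(params, n_steps=200_000, recorders=[sad, waves, div])

fit = fit_powerlaw_tail(sad.histogram, fit_range=(1 / 200, 1.0))
ws = wave_statistics(WaveStats(np.array(waves.boundaries)), div.diversity)
print(f"tail exponent tau = {fit.tau:.2f} +/- {fit.stderr:.2f}")
print(f"mean wave duration = {ws.mean_duration:.0f} (N ln N = {200*np.log(200):.0f})")
print(f"median diversity e-folding = {ws.median_decay_constant:.0f} (N = 200)")
```

prints

```
tail exponent tau = 1.55 +/- 0.03
mean wave duration = 1110 (N ln N = 1060)
median diversity e-folding = 221 (N = 200)
```

i.e. even this small 2·10⁵-collapse run shows the scale-free tail (still
a little below the large-N, long-run value τ ≈ 1.65–1.7), waves lasting
about N ln N steps, and diversity e-folding once every ~N collapses.

The same is available from the shell:

```sh
divwaves simulate -N 200 --gamma 1e-9 --steps 200000 --seed 42 --out run/
divwaves analyze --run-dir run/
divwaves fit-tail --sad run/sad.tsv
```

`simulate` writes `events.tsv` (one row per collapse: step, victim,
pre-collapse size, wave-boundary flag, rescale factor), `diversity.tsv`,
`sad.tsv` (log-binned histogram with metadata header), `waves.tsv`,
`config.yaml` and a `manifest.json` that suffices to reproduce the run
byte-for-byte.

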