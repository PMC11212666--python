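# moveflora

Trait-based lottery simulation of host-associated microbial communities
under long-distance host movement.

Migratory and dispersing animals carry their microbiota through
environments very different from where those communities assembled. How a
host microbiome responds — which taxa are lost, which environmental
microbes colonize, and whether repeated migrations eventually produce a
movement-adjusted community — is hard to observe directly. `moveflora`
provides a minimal, fully reproducible individual-based model for asking
these questions in silico: a zero-sum lottery community on a univariate
niche axis, driven through origin, movement-corridor, and destination
environments, with immigration from an environmental species pool whose
richness encodes the host's exposure.

## Model

A community of fixed size *J* holds individuals of species *s*, each
species carrying a niche trait *t<sub>s</sub>* ∈ [0, 1]. The environment
at generation *g* is a scalar optimum *E<sub>g</sub>* on the same axis
(think of it as the first principal component of all selective pressures,
host-imposed and abiotic together). Fitness combines Gaussian
environmental filtering with a limiting-similarity penalty:

```
f_s = exp( -(t_s - E_g)^2 / (2 σ_env^2) ) · exp( -c · L_s )
L_s = Σ_u  p_u · exp( -(t_s - t_u)^2 / (2 σ_comp^2) )     (trait overlap)
```

Each generation, *K* = ⌈d·J⌉ individuals die, sampled without replacement
with weights `1 − f_s / max f + ε` (a relative-fitness death bias with
floor ε that keeps drift alive). Every vacancy is refilled immediately:
with probability *m* by an immigrant from the environmental species pool,
otherwise by a local recruit proportional to survivor abundance.
Establishment filtering (multiplying recruitment weights by *f<sub>s</sub>*)
can act on both branches, immigrants only, or neither.

Movement scenarios place the selection optima at 0.3 (origin),
0.7 (movement corridor, e.g. the open ocean between two coastal regions)
and 0.4 (destination), with linear ramps over the first and last 10% of
each movement leg. *Irregular* movement is a one-off relocation; *regular*
movement cycles between origin and destination through the corridor.

Per generation the simulator reports species richness, Bray–Curtis
dissimilarity to a reference community, Rao's quadratic entropy on the
trait axis (functional diversity), the abundance-weighted mean trait, and
consecutive-generation turnover. Phase-level diagnostics include an
*acclimation index*: mean turnover in the first migration cycles divided
by the last cycles.

## Worked example

Simulate a one-off dispersal event with exposure to the environmental
pool concentrated in the movement phase:

```python
import moveflora as mf

pool = mf.build_synthetic_pool(richness=300, abundance_shape=1.0, seed=7)
cfg = mf.ScenarioConfig(movement_type="irregular", gens_burnin=200,
                        gens_movement=100, gens_residency=50)
schedule = mf.make_schedule(cfg)
dyn = mf.DynamicsParams(immigration_rate=0.005, recruit_weighting="immigration",
                        death_floor=0.5)
res = mf.run_simulation(pool, schedule, dyn_params=dyn, J=1000, seed=42,
                        immigration_by_phase={"movement": 0.10},
                        reference_generation=cfg.gens_burnin - 1)
s = res.summary
for phase in ("origin", "movement", "destination"):
    rows = s[s["phase"] == phase]
    print(f"{phase:12s} richness={rows['richness'].mean():6.1f}  "
          f"FD={rows['functional_diversity'].mean():.3f}  "
          f"BC={rows['bray_curtis_to_initial'].mean():.3f}  "
          f"trait={rows['mean_trait'].mean():.3f}")
```

prints

```
origin       richness=  50.3  FD=0.083  BC=0.403  trait=0.330
movement     richness=  59.7  FD=0.098  BC=0.645  trait=0.555
destination  richness=  58.4  FD=0.098  BC=0.998  trait=0.644
```

Read: during burn-in the community specializes on the origin optimum
(mean trait 0.33). Movement raises richness (new colonizers picked up en
route), pulls the mean trait toward the corridor optimum 0.7, and drives
Bray–Curtis dissimilarity to the pre-movement community toward 1 — by the
destination phase the microbiota has been nearly completely restructured.

The same machinery is available from the shell:

```
moveflora simulate --config cfg.yaml --out run/
moveflora experiment --preset fig1 --out exp/ --replicates 20 --base-seed 0
moveflora summarize --snapshots run/snapshots.tsv --pool pool.csv --out re.tsv
```

## Experiment presets

- `fig1_preset()` — movement type (irregular vs regular) × environmental
  pool richness (100 vs 1000 species), 20 replicates; per-cell aggregate
  trajectories of richness, functional diversity and dissimilarity, plus
  scalar metrics (richness gain during movement, movement-plateau mean
  trait, acclimation index).
- `selection_sweep_preset()` — irregular movement × environmental-filter
  width σ_env ∈ {0.05, 0.15, 0.5}; reports richness gained during
  movement per level (stronger selection admits fewer of the species
  encountered en route).

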