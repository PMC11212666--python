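# Methods

## The model

`moveflora` implements a zero-sum lottery model of a host-associated
microbial community. The community holds exactly *J* individuals at all
times. Species are characterized by a single niche trait on [0, 1]; all
conspecifics share one trait value. The environment is a single scalar
optimum on the same axis — deliberately not split into host-imposed and
abiotic components, on the view that from the microbe's perspective the
host is part of the environment and a univariate axis stands in for the
leading principal component of all selective pressures.

Each generation:

1. **Fitness.** Every present species gets
   `f_s = exp(-(t_s - E)^2 / (2 σ_env²)) · exp(-c · L_s)`, where `L_s` is
   the abundance-weighted mean Gaussian trait overlap with all *other*
   individuals (kernel width `σ_comp`, weight `c`). Fitness is computed
   once per species per generation against the pre-death community and
   reused for death and recruitment weights — a pure optimization, since
   all conspecifics are identical.
2. **Deaths.** `K = round(d·J)` individuals are removed, sampled without
   replacement with per-individual weights `1 − f_s/max f + ε`. Weighted
   sampling without replacement is implemented as an exponential race
   (each individual draws `Exp(1)/w`; the smallest K keys die), which is
   distributionally identical to successive weighted draws and fully
   vectorizes. The floor ε keeps even a perfectly adapted species mortal,
   so ecological drift never switches off and the equal-fitness limit is
   exactly the neutral lottery.
3. **Recruitment.** Each vacancy is filled independently: an immigrant
   from the environmental pool with probability *m* (weighted by pool
   relative abundance), otherwise a local recruit (weighted by survivor
   counts). `recruit_weighting` controls establishment filtering:
   `'fitness'` multiplies both branches by `f_s`, `'immigration'` only the
   immigrant branch, `'neutral'` neither. All weights are held at the
   post-death state; recruits do not affect each other within a
   generation.

The per-generation engine in `simulate.py` is an index-aligned, vectorized
implementation of the public `select_deaths` / `fill_vacancies` operations
(the test suite checks trajectory equality against the step-by-step
composition, and the one-step transition distribution against exhaustive
enumeration on a six-individual community).

## Movement scenarios

Selection optima: origin 0.3, destination 0.4 (similar habitats separated
by a dissimilar corridor), movement corridor 0.7. Movement legs of *G*
generations ramp linearly over their first and last `round(0.1·G)`
generations; ramps are endpoint-inclusive, which makes the return leg of
a regular cycle the exact time-reverse of the outbound leg. Irregular
movement: burn-in at the origin, one movement block, residency at the
destination. Regular movement: burn-in, then `n_cycles` out-and-back
cycles with residencies at each end.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `J` | 1000 | community size (individuals); large enough for ~10² coexisting species yet cheap to simulate |
| `death_fraction` d | 0.10 | expected fraction of J replaced per generation |
| `death_floor` ε | 0.05 | death-weight floor; sets the mortality-selection ceiling at (1+ε)/ε |
| `immigration_rate` m | 0.05 | probability a vacancy is filled from the pool |
| `sigma_env` | 0.05 | width of the environmental filter on the trait axis |
| `sigma_comp` | 0.1 | competition kernel width |
| `comp_strength` c | 0.5 | weight of the limiting-similarity penalty |
| pool richness | 100 / 1000 | low / high exposure levels in the experiments |
| `abundance_shape` | 1.0 | lognormal sigma of pool relative abundances |

The environmental filter width and the three optima are the model's
anchored quantities; everything else is configuration. The competition
kernel and its multiplicative combination with the filter are design
choices (the limiting-similarity mechanism spreads traits without ever
dominating environmental filtering at the defaults); both the kernel
width and the weight are exposed, and `c = 0` removes competition
entirely.

## Experiment presets: the migration study conditions

The presets define the conditions under which the directional
movement-ecology results are produced, and they differ from the module
defaults in four deliberate ways:

- **Exposure is concentrated in the movement phase** (`m = 0.005` in
  residence, `0.10` while moving). The pool-richness factor is about the
  environmental pool encountered *during movement*; a host moving through
  the environmental medium (open water, soil, air) samples far more of
  the "microbial soup" than a host at residence. This is also a
  structural requirement: with phase-constant exposure a community under
  a wide (weak) filter equilibrates with the entire pool before ever
  moving, so movement can add nothing and the selection-strength effect
  on richness gain inverts.
- **Establishment filtering applies to immigrants only**
  (`recruit_weighting='immigration'`): colonizers arriving from outside
  must establish through the environmental filter, while local
  reproduction is a plain lottery and selection among residents acts
  through mortality.
- **A gentler mortality bias** (ε = 0.5, maximum hazard ratio 3:1 rather
  than 21:1 at the module default). Residents maladapted to the current
  phase decline over tens of generations instead of being purged almost
  instantly.
- **Short residencies** (30 generations vs 100-generation movement legs).
  Together with the previous point this leaves regular migrants no time
  to fully re-specialize between trips: each cycle starts from a
  community still carrying the previous cycle's restructuring. That
  hysteresis is what produces the acclimation phase — elevated turnover
  over the first migration cycles that relaxes as the community settles
  into a movement-adjusted orbit. With long residencies and strong
  purging, every cycle is statistically identical and no acclimation
  signal can exist.

Two measurement conventions follow from the same reasoning. The
dissimilarity reference in experiments is the **pre-movement community**
(last burn-in generation), not the raw generation-0 draw: the initial
community is a multinomial sample of the whole pool, and drift away from
that artificial snapshot would otherwise dominate the Bray–Curtis signal.
The richness-gain baseline is mean richness over the **second half of
burn-in**, because the first half contains the assembly transient (excess
richness from the initial pool dump decays over 50–500 generations
depending on the filter width). The selection sweep uses a 600-generation
burn-in so that the baseline is quasi-stationary even at the widest
filter; the movement-type experiment, which runs only at σ_env = 0.05,
equilibrates within its 200-generation burn-in.

## Synthetic pools

The pool generator emulates a species list derived from an environmental
water sample: lognormal relative abundances (the canonical shape of
microbial abundance distributions) and uniform traits. It reproduces the
two features the experiments exercise — a realistic abundance skew and a
controllable richness — and nothing else: no phylogenetic or trait
correlation structure, no seasonal turnover of the pool itself, no
spatial structure among source communities. Passing tests therefore show
that the *mechanisms* (filtering, drift, exposure) behave as designed,
not that any particular real microbiota will show effects of a given
magnitude.

## Numerical choices

- All randomness flows through one `numpy.random.Generator` per run;
  experiment replicates derive their generators from
  `SeedSequence((base_seed, cell_index, replicate))`, a pure function of
  the design, so results are independent of execution order and
  bit-reproducible.
- The pairwise competition kernel over pool species is precomputed once
  per run (an S×S matrix), making a generation one matrix–vector product
  plus categorical draws; environmental fitness vectors are cached per
  distinct optimum value, which the piecewise-constant schedules make
  effective.
- Rao's quadratic entropy with |Δtrait| distance is computed by the
  sorted-trait identity `2 Σ (t_{k+1}−t_k) F_k (1−F_k)` (O(S log S)); the
  brute-force double loop serves as the test oracle. Rao with absolute
  distance was chosen as the simplest abundance-weighted trait-dispersion
  measure on a univariate axis; the abundance-weighted mean trait is
  emitted alongside so environment tracking can be read directly.
- If every recruitment weight underflows to zero (a community stranded
  many filter widths from the optimum), the recruit is drawn uniformly
  from the relevant source and a warning is logged.
- Bray–Curtis on equal-sized communities is identical on counts and
  relative abundances; users feeding external tables of unequal depth
  should normalize first.
- The acclimation index is NaN (with a warning) when late-cycle turnover
  is exactly zero, and requires at least 2k cycles.
- Degenerate ramps (`ramp_fraction·gens_movement` rounding to zero)
  produce a rectangular environmental pulse, which is permitted.

## Problem sizes

Default experiment sizes — J = 1000, pools of 100/1000 species, 20
replicates, regular runs of ~2800 generations — were chosen so a full
preset completes in about a minute on one CPU while keeping per-cell
standard errors well below the effect sizes of interest.

## Limitations

- One environmental pool per run; origin and destination draw from the
  same source community, and the pool itself never changes. Per-phase
  pools are a natural extension but are not built.
- No dormancy, no vertical transmission, no explicit host immune
  feedback, no priority effects beyond what the lottery itself produces.
- The trait axis is univariate by construction; trade-offs that require
  two independent niche dimensions cannot be represented.
- Generation counts, phase durations, and community size are model
  choices, not calibrated to any particular host system; results should
  be read as directional, not quantitative predictions.
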