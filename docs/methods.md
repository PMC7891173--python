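# Methods

## The model

`beegeneflow` models a honeybee population split into two tiers: a
*breeding* tier of `N_b` colonies per year whose queens are performance
tested and truncation selected, and a *passive* tier of `N_p` colonies that
is never selected but exchanges genes with the breeding tier.  Gene flow
between the tiers is summarized by two probabilities:

- `p` — the probability that a drone in a free (aerial) mating descends
  from a breeding colony.  When not set explicitly it defaults to the
  population share `N_b / (N_b + N_p)`.
- `q` — the proportion of passive queens whose dam is a breeding queen.

A colony's true breeding value is the breeding value of its worker group:
half from the queen, half from the mean of the drones the queen mated with.
This worker-group value also equals the expected breeding value of a
daughter queen reared from the colony.  Selection acts on colonies via two
genetic selection differentials, in breeding-value units: `S1` for colonies
chosen to produce the next breeding queens (maternal path, two-year
generation interval) and, under controlled mating, `S2` for colonies chosen
to found mating-station sister groups of drone-producing queens (DPQs;
paternal path, three-year interval from the DPQ's dam to the mated queen).

Writing `B_t` and `P_t` for the mean true breeding values of breeding and
passive colonies whose queens were born (and mated) in year `t`, the
inheritance paths give linear recursions.  Free mating:

    B_t = 1/2 B_{t-2} + (p+q-pq)/2 B_{t-4} + (1-p)(1-q)/2 P_{t-4} + (1+p)/2 S1
    P_t = q/2 B_{t-2} + (p+q-pq)/2 B_{t-4} + (1-q)/2 P_{t-2}
          + (1-p)(1-q)/2 P_{t-4} + p/2 S1

Station mating changes only the breeding-tier equation (passive queens
always mate freely):

    B_t = 1/2 B_{t-2} + 1/2 B_{t-3} + (S1 + S2)/2

Subtracting the passive from the breeding equation shows the genetic lag
`D_t = B_t - P_t` obeys its own contraction (free mating:
`D_t = (1-q)/2 D_{t-2} + S1/2`), so the tiers eventually progress in
parallel, separated by a constant lag.  The asymptotes are the closed
forms in `closed_form`:

| quantity        | free mating            | station mating                          |
|-----------------|------------------------|-----------------------------------------|
| annual gain ΔB = ΔP | (p+q)/(3+3q)·S1    | (S1+S2)/5                               |
| genetic lag D   | S1/(1+q)               | 6/(p+2q−pq)·(S1+S2)/5 − p/(p+2q−pq)·S1  |
| time lag T      | 3/(p+q)                | D / ΔB                                  |

The station-mating gain is the Rendel–Robertson ratio: summed selection
differentials over summed generation intervals (2 + 3 years).  Degenerate
denominators (`p+q = 0`, or `p+2q−pq = 0`) are reported as `inf` with a
`divergent` flag rather than raised, so sweeps over the whole unit square
complete.

The expected differential for truncation selection with intensity `i` and
estimation accuracy `rho` on colony values with standard deviation `sigma`
is `S = i·rho·sigma`.  `sigma` is deliberately an input: the colony-level
SD differs from the additive-genetic SD because queen and worker variances
are structured differently and selection erodes variance, and deriving it
is out of scope.

## Parity structure of the recursions

The free-mating recursions involve only lags 2 and 4, so even and odd
years form uncoupled sub-chains.  From the default all-zero initial state
the two chains are *identical* (B_{2k+1} = B_{2k+2}), which makes the
exact one-year difference `B_t − B_{t-1}` alternate forever between twice
the asymptotic gain and zero.  The asymptotic annual gain must therefore be
read parity-averaged, `(B_t − B_{t-2})/2`; `Trajectory.annual_gain`
implements this and `iterate`'s convergence detector compares gains and
lags two years apart (and requires the criterion to hold for four
consecutive years, because transients can pass through flat spots).
Station mating mixes lags 2 and 3, couples the parities, and its one-year
gain does converge to a single value.

## Initialization

The recursions start from an unselected base: all pre-start years at
level 0, with selection acting from year 1 on.  The base level and
switch-on year only affect transients, never the asymptotes, which is why
`InitialState` exists mainly as plumbing (five lagged years, enough for
the deepest recursion term).

## Convergence analysis

Each recursion is a linear recurrence with constant forcing; its transient
decays at the modulus of the dominant root of the homogeneous
characteristic polynomial (companion-matrix eigenvalues).  Even-lag
recursions are analyzed per parity chain (substitute `y = x^2`) and the
modulus is converted to a per-year factor by square root so all recursions
are comparable.  The gain recursions are posed on the level variable and
carry a structural unit root — the linear-growth mode — which is excluded
from the transient modulus.  On the parity chain both gain recursions
factor as `(y−1)(y+1/2)` resp. `(x−1)(x^2+x+1/2)`, giving a universal
per-year gain transient of `sqrt(1/2) ≈ 0.707`.  The lag recursions'
moduli depend on `(p, q)` and approach 1 as `p, q → 0`: at `q = 0` under
station mating the per-year modulus is `~0.9` for `p = 0.5` and exactly 1
at `p = q = 0`.  This quantifies why 20-year evaluation windows
systematically under-read the lag (and over-read predictions) for nearly
self-sufficient passive tiers, while the closed forms remain exact in the
limit.  `years_to_converge` reports the analytic modulus, the first year
within `eps` of the asymptote, and an empirical geometric rate fitted to
the late-time distance sequence (consistent with the modulus to within a
few percent for the real-rooted lag recursions).

## The simulator

`simulator` is an individual-based, vectorized implementation of the same
population structure:

- **Cohorts.**  Per year and tier, arrays of queen values and per-colony
  sire (drone-mean) values; colony value = (queen + sire)/2 exactly.
- **Base population** (years −3…0): queens i.i.d. normal with additive SD
  `sigma_a` (default 1), colonies assembled by random mating.
- **Inheritance.**  Infinitesimal model: a daughter deviates from her dam
  *colony*, and a drone from his dam *queen*, by a Mendelian-sampling draw
  of SD `sigma_a/sqrt(2)` per component.  Only expectations matter for the
  validated quantities; the variance convention keeps the population
  variance roughly stationary.
- **Selection.**  An index of accuracy `rho` (true colony value plus
  noise scaled by `sqrt(1-rho^2)`·SD; default `rho = 0.8`) replaces a full
  BLUP evaluation.  The top `dam_fraction` (default 20%) of breeding
  colonies two years back supply the new breeding queens in equal shares;
  under station mating, `n_stations` colonies three years back are
  selected to found the stations, each with `dpqs_per_station = 8` sister
  DPQs whose drones mate the year's breeding queens (one station per
  queen, uniform).  Realized differentials `S̄_1, S̄_2` are recorded as the
  selected-group mean minus the cohort mean of *true* values, so all
  predictions are driven by measured, not assumed, differentials — the
  validation is self-calibrating with respect to `rho`, the selected
  fraction and drone numbers.
- **Free mating.**  Every queen mates `drones_per_mating` drones (default
  12; the biology allows up to 20).  Drone dams are breeding colonies with
  probability `p` and of age uniform on {1, 2, 3} years (mean two years,
  as are passive-dam ages); breeding-queen dams are fixed at two years and
  the DPQ-granddam path at three, matching the generation-interval layout
  of the analytic model.
- **Genetics modes.**  `aggregate` (one value) or `maternal_direct` (queen
  and worker components with heritabilities `h2_m`, `h2_d` and correlation
  `r_md`, scaled so the total SD is `sigma_a`; defaults 0.53/0.34/−0.53).
- **Reproducibility.**  One global seed; replicate `r` uses the RNG stream
  seeded by `(seed, r)`, so replicates are independent yet individually
  reproducible and outputs are byte-identical across runs.

What the simulator does *not* emulate: inbreeding, genetic drift in the
sense of finite-locus genomes, pedigree BLUP and its information
structure, Bulmer-effect variance erosion beyond what truncation selection
produces naturally, spatial mating structure, or reproductive advantages
of high-value drones.  Passing tests therefore show that the gene-flow
bookkeeping is right under the model's own assumptions, not that real
breeding programs realize these differentials.

## Validation design

For each scenario the per-year summaries are averaged over replicates;
realized `S̄_1`, `S̄_2` and the simulated annual gains and lag are averaged
over years 8–17 (differentials only up to the last cohort actually
selected in-horizon, `t ≤ years−2` resp. `years−3`).  The window starts at
year 8 because the realized differentials stabilize after the start-up
years.  Each scenario contributes three paired points (breeding gain,
passive gain, lag); agreement is summarized by the least-squares slope
through the origin (comparison against the diagonal equality line) plus
the squared Pearson correlation, with an ordinary with-intercept fit
reported alongside.  The default grid is desk-scale: equal tiers of 250 or
500 colonies, `q ∈ {0.5, 0.75, 1}`, both mating systems, 10 replicates,
20 years — q below 0.5 is excluded from the headline comparison precisely
because of the convergence argument above.

`reconstruct_passive_colony_mean` recovers passive colony means from queen
means alone (`P̄_t = ½P̄^Q_t + ½(p/3·ΣB̄^Q_{t−i} + (1−p)/3·ΣP̄^Q_{t−i})`,
i = 1..3), for settings where passive worker groups are not tracked; since
this simulator does track them, the reconstruction is tested against the
directly simulated means.

## Numerical choices

- Convergence tolerance in `iterate`: `1e-9` on parity-matched gain and
  lag differences, over four consecutive years.
- Root finding via `numpy.roots` (companion matrix); the structural unit
  root is identified within `1e-8`; modulus ties are resolved by reporting
  the full root set.
- Grid sweeps treat zero denominators as flagged `inf`, never exceptions.
- Long-run oracle iterations use 400 years (free mating) and 1200 years
  (station mating) so that even the slowest corner of the parameter grid
  (per-year modulus ≈ 0.96 at `q = 0`) is within `1e-6` of its asymptote;
  both run in well under a second.
- The acceptance study sizes (250/500 colonies, 10 replicates) are the
  package's desk-scale defaults; the full study design scales to thousands
  of colonies unchanged.

## Known limitations

- Means only: no variance dynamics, no inbreeding, hence strictly linear
  long-term gain — unrealistic over many generations by design.
- The accuracy-`rho` index is not a BLUP; realized differentials (and
  negative per-component differentials under strong negative `r_md`) will
  differ from programs using pedigree evaluation.
- The analytic model fixes drone-dam age at two years where the simulator
  uses ages 1–3; the two agree once gain is linear, which is part of what
  the validation checks.
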