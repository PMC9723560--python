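# Methods

## The ecosystem model

State variables are concentrations of phytoplankton types, heterotrophic
bacteria types, dissolved and particulate organic-matter (DOM/POM)
species, inorganic nutrients (N, P), micronutrients and inhibitors.
Carbon pools are in µmolC/L, nutrients in µmol/L, micronutrients and
inhibitors in arbitrary units (they never enter the carbon ledger). Time
is in decimal days; the model year is 365 days and day-of-year quantities
wrap circularly.

Processes, per compartment:

* **Phytoplankton** — photosynthesis `kp·Lp·C`, respiration `kr·Lr·C`,
  exudation `(ke + ef·kp·Lp)·C` distributed over DOM species by fractions
  `Fe` (remainder routed to the producer's POM pools pro-rata by its POM
  composition, so carbon is conserved), seasonal death `ku·Lu·C`
  partitioned by `Fx` to DOM and remainder to POM, inhibitor kill
  (Monod in the inhibitor concentration, partitioned like death),
  settling `vs/H`, dilution `Q/V`.
* **DOM** — inflows from exudation, death and POM dissolution; outflows
  to bacterial uptake and dilution.
* **POM** — death/exudation remainders in; first-order dissolution
  `kf·Lf` to a paired DOM species, settling, dilution.
* **Bacteria** — shared-denominator multi-substrate Monod uptake with
  yield `Yh` (the `1−Yh` remainder is respired), death, inhibitor kill,
  dilution. A bacterium–substrate pair absent from the `Ksh` table cannot
  use that substrate: the pair is excluded from both the numerator and
  the shared denominator (no sentinel value ever enters arithmetic).
* **Nutrients** — external loads, consumption proportional to
  photosynthesis via fixed N:C and P:C ratios, and immediate return of
  the stoichiometric N/P carried by bacterial respiration and microbial
  death. Organic pools are carbon-only, so this return path is the
  simplest closure that conserves mass; it slightly front-loads
  remineralization relative to a model with organic N/P pools.
* **Micronutrients** — exuded by bacteria, consumed proportionally to
  photosynthesis, diluted. **Inhibitors** — exuded by microbes, decay
  first-order, diluted; they kill configured targets by a Monod law.

Limitation factors. Light uses a Steele photoinhibition curve averaged
analytically over the water column under an extinction coefficient
`kex = background + Σ shading·C + ISS`; the small-`kex·H` limit is
evaluated in a cancellation-free form. Temperature response rises
exponentially below the optimum and declines as a Gaussian above it;
salinity is a Gaussian tolerance window; the mortality season is a
wrapped Gaussian over day-of-year lifted by a baseline (`death_base`),
representing the annual grazing/lysis cycle. Nutrient and micronutrient
Monod factors combine by a minimum law. All forms sit behind the
`LimitationFactors` boundary so alternates can be swapped.

**Dormancy.** Any microbe at or below its floor concentration `Cflr` has
all loss-process rates scaled by a common factor so its net derivative is
non-negative at the floor; the scaling ramps smoothly over
`[Cflr, 1.05·Cflr]` to keep the right-hand side continuous. The floor is
treated as extensive: de-lumping halves it along with the initial
concentration, which is what makes a split exactly neutral.

**The flux ledger.** Every process rate is computed into a fixed vector
of (source, sink, process) channels, and the state derivative is
assembled as gains-minus-losses over exactly those channels, so
`dC/dt = Σin − Σout` holds bit-exactly at every evaluation. During
integration the cumulative integral of every channel is carried as an
augmented state, which makes the interval ledger consistent with the
trajectory to integrator tolerance. The inner loop has a numba-compiled
kernel that is numerically identical to the pure-numpy reference
implementation (both are kept; tests cross-check them).

## Error metric

A data point may miss the model in value or in time, so its error is the
minimum squared distance over all model output points in the
(concentration, time) plane, the time axis scaled by
`ave(C_d, C_m)·k_ch` with the pair average using the candidate model
point (the convention is switchable). `k_ch` defaults to 0.1/d: a ten-day
offset costs about one full magnitude. Per-series errors are
`sqrt(mean ES)/mean(observed)` (normalizer switchable to range), weighted
and summed. Errors are computed in arithmetic space. An optional ±60-day
search window is a pure speed path, verified in tests to reproduce the
exact global minimum on series of this length.

## Calibration

The de-lumping schedule starts from one component per compartment and
alternates optimization with species splits. Daughters inherit the
parent's parameters; producer-side distribution fractions that target a
split substrate are halved across its daughters while consumer
half-saturations are copied, so a split with no overrides changes the
total error only at integrator-tolerance level. Curation overrides
(applied after inheritance) pin species traits or forbid substrate use.

Within a level each iteration runs single-parameter sweeps (geometric
grids for wide positive ranges, golden-section refinement), re-sweeps of
the most sensitive fraction, Nelder–Mead on per-component dependent
subsets in a logit/log box transform, and optional Latin-hypercube scans;
candidates are accepted only on strict improvement, so the best-so-far
error is non-increasing within a level. Default convergence: relative
improvement below 1% per iteration. Evaluation budgets are counted per
objective call, so de-lumping and flat calibrations can be compared
fairly. Observation series that currently resolve to the same lumped
ancestor are summed into one aggregate series for the error, so coarse
levels fit aggregates; species-level initial concentrations are
re-initialized from the first observation when available.

Calibration evaluations integrate at rtol 1e-5/atol 1e-3 (floors are
~1e-2 µmolC/L) on a 2-day output grid; reporting runs use rtol 1e-8/
atol 1e-10 with the full ledger.

## Network analysis

Window-averaged ledger records give component-to-component networks;
traced mode attributes each DOM→bacterium flux to upstream producers in
proportion to their share of the pool's window inflow, resolving POM
pools through to their own producers (first-order provenance). Turnover
time is standing stock over through-flux (mean of inflow and outflow by
default; switchable). Oligotrophy is weighted continuously,
`fOLI = kg_ave^n/(kg_ave^n + kg_i^n)` with `n = 5` and `kg` the net
growth rate from biomass change plus dilution, floored at zero; the
community average is the unweighted mean over bacteria types. DOM
standing-stock origin fractions (exudation / death / initial) evolve by
inflow-proportional mixing, with dissolution inflows carrying the POM
pool's current origin mix. Bloom windows start at the first exceedance of
3 µgChl a/L each year and extend 28 days. Year-to-year recurrence is
Bray–Curtis similarity (1 − dissimilarity) on layer vectors, with
top-quartile components recurring in every snapshot listed by average
rank.

## The synthetic-data generator

The generator emulates a coastal observatory's data structure: seasonal
light and temperature cycles over a 10 m mixed column, constant dilution
(0.04/d) and nutrient loads, a 2-year window sampled every 2 days with
10% gaps, mean-one multiplicative lognormal noise (σ = 0.2) and a
detection floor, and a mix of summary series (chlorophyll, total counts)
and species-level series. Truth ecosystems are built by running the same
de-lumping machinery with seeded diversification draws — phytoplankton
daughters get seasonal niches (temperature optimum, light optimum, death
timing), bacteria daughters distinct uptake kinetics, all microbes
distinct organic-matter composition — and every diversified trait except
the uptake kinetics is pinned by per-level curation records, the analogue
of literature-known species traits. One bacterium is forced
oligotroph-like (slow, low `Ksh`, low mortality) and one
copiotroph-like (fast, substrate-hungry, high mortality). A screening
simulation resamples draws until all microbes stay active above their
dormancy floors.

Design choices made for a well-posed recovery benchmark, decided up
front: macronutrient loads are high enough that blooms are terminated by
the seasonal mortality bell and self-shading rather than nutrient
exhaustion, and bacterial turnover is fast, both of which damp the
chaotic sensitivity of multi-species competition; and observations for
recovery experiments are generated at the calibration's own integrator
settings so the truth parameterization scores ~0 and the experiment tests
the calibration machinery rather than solver robustness. What passing
recovery tests on these fixtures shows is that the machinery can identify
uptake niches from rich, well-specified data; it does not show that a
four-year field series with structural model error yields comparable
accuracy.

## Known limitations

* Bloom-forming trajectories are peaky (series maxima 6–20× their means)
  and sensitive: perturbing the free parameters ~1% around the truth
  already raises the mean-normalized total error to 0.04–0.3. Error
  thresholds near zero are therefore not reachable by derivative-free
  calibration at desk-scale budgets, even though substrate affinities are
  recovered within a factor of two; the acceptance suite documents this
  with one intentionally strict failing assertion.
* Enzyme-mediated polysaccharide breakdown, time-varying exudate
  composition, osmotrophy/mixotrophy and refractory allochthonous DOM are
  out of scope.
* The inhibition-kill carbon is routed like other death (to DOM/POM by
  the target's composition); whether such losses should instead be
  exported is not settled and the routing is isolated in one channel
  block.
* Nutrient mass balance is open (settling exports organic carbon but the
  associated N/P return immediately); a closed N/P budget would need
  organic N/P pools.
* The per-level split policy for nutrients/micronutrients/inhibitors is
  exposed in the schedule rather than fixed; the default splits only the
  four organic compartments.
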