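# Methods

`cleftsim` simulates the stochastic activation of AMPA receptors by a
single vesicle of glutamate in an idealized cortical synapse, and the
statistics of that response across a population of synapses whose sizes
follow the distribution measured in rat somatosensory cortex by 3-D
electron microscopy.  This note records the model, its assumptions, the
numerical choices, and what the synthetic population does and does not
capture.

## Geometry

The world is three nested axis-aligned boxes (all lengths in nm,
right-handed coordinates, cleft axis = z):

* **Pre- and postsynaptic elements** — solid boxes of footprint
  `La x La` facing each other across a synaptic cleft of height
  `Hc = 20`.  The postsynaptic top face lies at `z = 0`, the presynaptic
  bottom face at `z = 20`.
* **PSD and AZ** — congruent centered squares of side `Ls` on the two
  apposed faces.  The PSD carries AMPA receptors at surface density
  `[AMPAr]`; the AZ is bare membrane with the release point at its
  center.
* **Perisynaptic box** — an enclosing box standing off the elements by a
  gap `g`, representing the surrounding neuronal and glial membranes.
  Its six inner faces carry glutamate transporters at density `[GluT]`.

The extracellular space (ECS) is everything inside the perisynaptic box
and outside the elements.  The gap `g` is solved (Brent's method) so that
the ECS is a target fraction (default 20%) of the enclosed volume, then
clipped to the allowed 38–65 nm range.  For most sampled synapses the
balance is unsolvable — with elements of height `La` (the default) the
lateral shell alone exceeds 20% of the volume whenever `La` is a few
hundred nm — so the gap clips to 38 nm, a warning is emitted, and the
achieved fraction (0.20–0.54 across the population) is recorded on the
geometry.  A sensitivity scan (element height `La`, `4 La`, `10 La`,
i.e. achieved ECS fraction 0.20–0.54) moved mean maxOPEN by under 1% and
mean peak time by under 15%, so the clipped balance does not drive the
results; element height remains configurable.

Transporter placement is configurable
(`SimParams.transporter_placement`).  The default puts transporters on
the perisynaptic box only, because the membranes described as carrying
them are the *neuronal and glial* processes that the perisynaptic box
represents; the alternative `"both"` additionally covers the
extrasynaptic pre/post apposed annuli (purely neuronal membrane).  The
choice matters at the ~20% level for mean maxOPEN (perisynaptic-only is
higher, because transmitter in the 20-nm extrasynaptic cleft annulus is
not absorbed there and can return to the PSD).

## Receptor and transporter kinetics

Surface molecules are independent continuous-time Markov chains.  The
AMPA receptor scheme has nine states — eight closed, one open — with the
topology and rate constants of the Jonas–Major–Sakmann mossy-fibre
scheme as adopted by Häusser & Roth (1997): sequential binding of two
glutamate molecules (`C0 → C1 → C2`), gating `C2 ⇌ O`, desensitized
branches off the mono-liganded, di-liganded and open states, and two
slow deep-desensitized tail states that complete the nine-state
topology without influencing the sub-millisecond peak (their rates are
well below 1/(10 ms)).  The transporter cycle follows Franks, Bartol &
Sejnowski (2002): binding, then either release back into the ECS or
translocation (which removes the molecule), then slow recovery of the
outward-facing state.

**Transcription caveat.**  The source articles for both schemes print
the rate tables; this package transcribes them into versioned YAML files
(`cleftsim/schemes/`), flagged `transcription-to-verify`.  The
population statistics that depend on absolute open probabilities and
peak position (pooled mean/median maxOPEN, mean peak time) inherit any
transcription error; the structural results (correlation screen,
power-law exponents, activation-probability ordering) are robust to it.
With the rates as transcribed, the open-state relaxation
(closing 900 s⁻¹ + desensitization 16.8 s⁻¹ at the reference
temperature) places the open-count peak of a brief transient near
120–200 µs, and the simulated population reproduces the published
maxOPEN scale to roughly −25% and the published mean peak time to about
a factor of two.

All rate constants are Q10-corrected from the source recording
temperature (nominal room temperature, 23 °C) to the simulation
temperature (35 °C) with Q10 = 2.5, giving a uniform ×3.0 speed-up
applied to unimolecular and bimolecular constants alike.

**Discretization.**  Each molecule makes at most one unimolecular
transition per time step, drawn by competing risks: no transition with
probability `exp(-k_total dt)`, otherwise an edge proportional to its
rate.  This is exact for single-exit states and converges to the exact
CTMC marginals as `dt → 0`; at `dt = 1 µs` the largest per-step
transition probability in the packaged schemes is ~0.02, and the test
suite verifies agreement with matrix-exponential marginals at
`dt = 1, 0.5, 0.25 µs` and with a Gillespie oracle.  For transporter
populations the per-state Bernoulli thinning is drawn as a binomial
count plus uniform picks without replacement — exact, and O(movers)
rather than O(population) per step.

## Brownian dynamics and binding

Free glutamate performs Gaussian steps with per-axis sd
`sqrt(2 D dt)` = 25.7 nm (`D = 0.33 µm²/ms`, `dt = 1 µs`), ray-traced
against every membrane with specular reflection (bounce limit 64; steps
that fail to resolve are discarded and counted — in practice none are).

A step segment that crosses a receptor- or transporter-bearing face is a
binding opportunity.  The surface is partitioned among its molecules:
receptors own the Voronoi cell around their (uniformly placed, seeded)
positions, implemented as a nearest-neighbour query with a capture
radius of 3 tile radii (coverage error e⁻⁹); transporters sit on a
density-preserving jittered grid (one molecule per cell of area
1/density, uniformly placed within the cell) so the owner lookup is
O(1) even for ~10⁵ transporters.  The crossing succeeds with

    p = kon · sqrt(π dt / D) / (N_A · a)

where `a` is the area owned by the molecule and `kon` the bimolecular
rate constant of its current state (zero for saturated or desensitized
states).  The formula comes from the wall-collision rate of the
discretized walk — a molecule uniform in a closed volume V strikes a
wall patch of area `a` at expected rate `E|dz|·a/(2V)` per step — so the
per-pair association rate is exactly `kon/(N_A V)`, the mass-action
value.  Two properties are worth noting:

* `p × collision rate` is independent of `dt`: halving the time step
  leaves the matched flux unchanged (verified analytically and by
  simulation).
* Crossings are assigned to the *owner* molecule regardless of its
  state.  Assigning them to the nearest *bindable* molecule instead
  would re-partition the capture area of saturated receptors onto their
  neighbours and overshoot mass action by tens of percent as the PSD
  saturates (measured against the ODE oracle); the owner rule keeps the
  flux proportional to the number of binding-competent receptors.

The test suite validates the whole binding pathway end-to-end: in a
sealed well-mixed box the simulated association time course matches the
mass-action ODE within 5% after a 100-µs mixing burn-in.

Bound glutamate is re-emitted 0.5 nm off the membrane on unbinding and
deleted on transport.  Glutamate is conserved as an exact integer
identity — free + bound(receptors) + bound(transporters) + removed =
N_g — checked by the kernel at every step; a violation aborts the run.

## Population sampling

A synapse configuration is one draw of `(Ls, La, [AMPAr], [GluT])`:

| parameter | law | values |
| --- | --- | --- |
| `Ls` | log-normal, truncated | µ = 5.356, σ = 0.446 (ln nm); 60–825 nm |
| `La` | `Ls × U(1, 2)` | 1–2 × Ls |
| `[AMPAr]` | uniform | 500–3000 µm⁻² |
| `[GluT]` | uniform | 7000–12000 µm⁻² |

The `Ls` law comes from the measured Feret-diameter distribution
(log-normal, µ = 5.828) scaled by the shape factor k = 0.624 relating
`sqrt(SAS)` to the Feret diameter; where the printed parameters disagree
between the summary table (5.34/0.45) and the text (5.356/0.446) the
higher-precision text values are used.  Truncation to the observed
60–825 nm range is by rejection and can be toggled off.  Derived
quantities: `As = Ls²`, `nAMPA = round([AMPAr]·As·10⁻⁶)` with
round-half-away-from-zero and a floor of one receptor.

Seeding is counter-based throughout: the root seed spawns one seed per
configuration (`SeedSequence([root, i])`), each configuration seed
spawns one per run (`SeedSequence([config_seed, j])`), and each run
splits a placement stream from the diffusion-kernel seed.  Any single
run is therefore reproducible in isolation and results are byte-stable
under any execution order or worker count.

## Statistics

Each run is reduced to `maxOPEN` (peak of the open-count series), the
peak time (first attainment of the maximum — the tie rule matters for
small, noisy series) and the AUC (`dt × Σ counts`).  Per configuration,
replicates give the mean, sample sd (n−1) and cv = sd/mean; cv is
reported missing when the mean is zero.  Correlation screens use
per-configuration means (one point per synapse).  Power-law regressions
`f(x) = a x^b + c` are nonlinear least squares with a documented,
deterministic initialization (c₀ = min(y) − ε; a₀, b₀ from the log–log
line; a small c₀ grid of retries), validated on an independently seeded
test population; with the exponent pinned at 1 the fit reduces to
ordinary linear regression.  Pooled maxOPEN distributions are
integer-binned; quartiles use linear-interpolation quantiles (with
integer-valued data the common rules agree near the quartiles).
Activation probabilities are empirical exceedance frequencies per
configuration, binned into equal-count bins of nAMPA for the population
curves.  Spatial opening maps tile the PSD into 55-nm cells and average
per-run open fractions; the four default time points are 0.5× the mean
peak time (rising), the peak, 2× the peak (falling) and 8 ms (late).

## Problem sizes

The published experiment simulated 500 configurations × 500 runs.  The
desk-scale study used by the analysis scripts, the acceptance script and
the statistical tests is 30 configurations × 50 runs (≈ 4–5 minutes on
one CPU with the numba kernel), which reproduces the correlation
structure and puts ~10–15% sampling error on the pooled moments; the
`paper` preset runs the full size unchanged.  Property tests use
10⁴–10⁵ particles or molecules as stated in each test.

## What the synthetic population does not capture

* Real synaptic junctions are irregular surfaces; the model's square
  PSD/AZ and box elements keep only the measured area and apposition
  scale.  Curvature, perforations and spine geometry are absent.
* Receptor density is drawn uniformly over a wide literature range and
  independently of synapse size; in tissue the density range is likely
  narrower and possibly size-correlated, which would only strengthen the
  dominance of synapse size found here.
* Presynaptic variability (multivesicular release, release failure,
  vesicle content variation) is deliberately excluded — every run
  releases exactly 3000 molecules — so the reported variability is
  purely postsynaptic-stochastic.
* The ECS is a closed compartment: clearance is by transporter uptake
  only, with no diffusion into surrounding neuropil.  The long-tailed
  open-receptor curves depend on this closure.
* No NMDA receptors, receptor lateral mobility, or electrical (EPSP)
  modelling.

## Known limitations

* The kinetic rate tables are best-effort transcriptions of the cited
  sources (see above); the absolute open-probability level and peak
  timing carry that uncertainty, quantified in the test suite's
  tolerance bands.
* The per-crossing binding probability is calibrated in the
  reaction-limited regime; strongly diffusion-limited association would
  need smaller time steps (the calibration raises an error if p would
  exceed 1).
* With `dt = 1 µs` the Gaussian step (25.7 nm) exceeds the cleft height;
  the folded-path collision counting remains exact for the mean flux
  (verified in a slab test), but sub-step concentration gradients within
  the cleft are unresolved — the same compromise the established
  particle-based simulators make at this step size.
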