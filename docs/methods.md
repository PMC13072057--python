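# Methods

This document describes the model implemented by `hemodose`, the default
parameter values and why they were chosen, what the synthetic cohort
generator does and does not emulate, and the numerical conventions used
throughout. Statements about study behavior are limited to properties the
test suite actually computes.

## 1. Circulation model

The circulation is represented as a set of parallel organ compartments
(`hemodose.circulation`). Compartment `o` has a blood volume `V_o` (mL) and a
blood flow `Q_o` (mL/min); the compartments partition the whole blood pool
and the cardiac output exactly:

- Σ V_o = total blood volume, Σ Q_o = cardiac output;
- sex-specific reference totals: male 5.3 L and 6.5 L/min, female 3.9 L and
  5.9 L/min (ICRP Publication 89 reference values);
- mean transit time of a compartment: τ_o = 60·V_o/Q_o seconds;
- stationary occupancy of a compartment: V_o / V_total.

The packaged per-compartment tables (`hemodose/data/icrp89_{male,female}.csv`)
list 16 compartments (aorta, bone, brain, bronchi, fat, large arteries, large
veins, lungs, lymph nodes, skeletal muscles, skin, stomach, esophagus,
superior vena cava, thyroid, and a residual body). A literal physiological
flow assignment is impossible in a parallel topology for conduit structures —
the aorta and the lungs carry essentially the whole cardiac output *in
series* — so the shipped flow fractions for those compartments are
plausibility-scaled, and the `residual_body` compartment is recomputed at
load time so both conservation sums close exactly. Users can supply their own
table (`build_reference_model(sex, parameter_table=...)`); validation rejects
tables whose fractions exceed unity and names any missing compartment.
Because the table is an adaptation, no quantitative result in the test suite
depends on its specific entries: all numeric transport tests use small
explicit toy models.

## 2. Blood-dose Monte Carlo

`hemodose.simulator` discretizes the blood pool into `n_particles`
computational particles, each carrying a compartment index, a remaining
residence time and a cumulative dose.

**Transport.** Particles are initialized from the stationary distribution
(counts proportional to `V_o`), with residual residence time uniform on
[0, τ_o] in the default fixed-residence mode or exponential with mean τ_o in
exponential mode. When a particle's residence expires it is reassigned to a
compartment with probability proportional to blood flow `Q_o` (self-returns
allowed, as in a well-mixed central pool) and receives that compartment's
residence time. Fixed residence (τ_o exactly) is the default because it
reproduces the deterministic transit-time picture of compartmental blood-flow
dosimetry; the exponential option models fully mixed compartments and is used
in the relaxation tests.

**Dose accrual.** Each treatment fraction delivers the per-fraction organ
DVHs over a beam-on schedule: `n_fields` fields of `field_beam_on` seconds
each (optionally separated by gaps). The cumulative beam-on clock `B(t)` is
piecewise linear; a particle resident in an irradiated organ during
[t₀, t₁] accrues `D · (B(t₁) − B(t₀)) / T`, where `D` is a dose level drawn
once per visit from the organ's DVH by inverse-CDF sampling and `T` is the
fraction's total beam-on time. This is the "dose rate = DVH draw / beam-on
time" model of HEDOS-style frameworks: a blood element that spends the whole
beam-on period in the organ accrues exactly its DVH draw.

**Fractionation.** A course of `n_fractions` fractions divides the planning
(course) DVH dose axis by `n_fractions` and, in the default
`resample_each_fraction` mode, re-randomizes particle positions and dose
draws independently each fraction — blood mixes completely between daily
sessions, which is conservative and realistic for inter-fraction intervals of
a day. The alternative `scale_single_fraction` mode simulates one fraction
and multiplies by `n_fractions`; it has the same mean but a wider spread
(no inter-fraction averaging) and is provided only as a fast approximation.

**Output.** Per-particle course doses are reduced to an empirical survival
curve (the blood DVH) on the standard dose grid, and the metric set
`Dmean, D90%, D70%, D50%, D30%, D10%, D2%, V0.9Gy` is reported. V0.9Gy —
the fraction of blood receiving at least 0.9 Gy — is included because ~1 Gy
is the scale of lymphocyte radiosensitivity (LD50 for lymphocytes is about
2 Gy, and meaningful depletion begins well below that).

### Default simulation parameters

| parameter | default | rationale |
|---|---|---|
| `n_particles` | 1,000,000 (`SimulationConfig`); 10,000 in the study pipeline | 10⁶ gives per-metric Monte-Carlo errors well below the DVH bin width; 10⁴ keeps a 36-plan study under a minute while keeping the standard error of blood Dmean ≪ between-patient spread (verified by the particle-scaling test) |
| `dt` | 0.05 s | time-grid granularity for the literal stepping kernel; the production path is event-driven and exactly equivalent (see §5), so `dt` has no effect on course results |
| `residence_mode` | `"fixed"` | deterministic V/Q transit times, the standard compartmental assumption |
| `fraction_mode` | `"resample_each_fraction"` | full inter-fraction blood mixing |
| `bin_width` | 0.01 Gy | DVH dose resolution; metric tolerances in tests are stated in units of this bin |
| fractions | 33 | standard head-and-neck conventional fractionation (60 Gy / 1.8–2 Gy per fraction) |
| IMRT schedule | 9 fields × 40 s | typical step-and-shoot IMRT delivery time structure |
| IMPT schedule | 4 fields × 30 s | typical pencil-beam-scanning delivery: fewer fields, shorter beam-on |

## 3. Synthetic cohort generator

Real treatment plans come from a commercial optimizer and cannot be
regenerated here; the analysis, however, consumes plans only through their
organ DVHs, target-coverage indices and delivery schedules. The generator
(`hemodose.cohort`) emulates exactly that interface.

**What it emulates.**

- A cohort of `n_patients` (default 20; 75% male) head-and-neck-like
  patients, prescriptions 60 Gy (PTV1) and 52 Gy (PTV2) in 33 fractions.
- Six plan conditions per patient: {IMRT, IMPT} × {Conv, BVS-90%, BVS-80%},
  where BVS-x% is a blood-vessel-sparing constraint limiting the conduit
  vessel mean dose to x% of the same patient's conventional plan.
- Organ DVHs as smooth logistic survival curves whose mean dose is drawn
  from lognormal organ-class priors (course mean dose):
  conduit vessels median 5.5 Gy (σ_log 0.35), near-field neck organs 3.0 Gy
  (0.40), low-dose-bath tissues 0.7 Gy (0.30), distal organs 0.3 Gy (0.40).
  The priors were set, before any end-to-end run was scored, so that
  non-outlier blood mean doses land in the ~1–2 Gy range typical of
  head-and-neck circulating-blood dosimetry.
- IMPT multiplies all non-vessel organ doses by `impt_low_dose_factor`
  (default 0.55): protons shrink the low-dose bath, while vessel doses are
  driven by target proximity and stay put between modalities.
- BVS conditions rescale the vessel DVH dose axes so the vessel mean dose is
  *exactly* 0.9 / 0.8 of the conventional plan, plus a small localized dose
  redistribution consistent with re-optimization: brain hot-spot up by
  1–3% and esophagus mean dose down by 5–10% (half effects at BVS-90%).
- PTV DVHs are piecewise-linear survival curves with an enforced hot-spot
  objective D0.1% < 1.01×prescription and a homogeneity index
  HI = D5%/D95% drawn within 1.02–1.10; conformity index
  CI = 100·V95%iso/V_PTV lands above 96.
- One optional outlier patient (default on, the last patient) whose tumor
  overlaps the conduit vessels: vessel course mean doses of 50–58 Gy and
  almost no vessel-sparing headroom (achieved scalings 0.995 / 0.99 instead
  of 0.9 / 0.8), producing a blood dose several times the cohort median that
  barely responds to BVS constraints.

**What it does not emulate.** No spatial dose distributions, no optimizer
mechanics or beam models, no organ-at-risk hard constraints other than the
vessel-mean control, no intra-fraction breathing or cardiac-phase effects, no
patient anatomy beyond the compartment table, and no correlation structure
between organs beyond the shared patient-level class draws. The DVH *shapes*
(logistic organs, piecewise-linear targets) are convenient smooth families,
not fits to any clinical dataset.

**A deliberate design choice.** Clinical planning objectives often pair a
hot-spot cap (D0.1% < 101% of prescription) with a cold-spot goal
(D98% > 99%). Those two together would force HI < 1.0202, while realized
head-and-neck plans routinely show HI up to ~1.10 — objectives are goals the
optimizer trades off, not guarantees, and the cold shoulder is where plans
give. The generator therefore enforces the hot-spot cap strictly and lets
D98% fall below 99% of prescription; that cold-shoulder relaxation is what
carries HI through the 1.02–1.10 envelope.

## 4. Statistics

`hemodose.stats` implements the paired, nonparametric within-modality
analysis:

- **Friedman test** across the three constraint levels with average-rank tie
  correction. The p-value is exact by default at study sample sizes: a
  dynamic program over doubled-rank column sums for k = 3 columns (n ≤ 500),
  generic permutation enumeration while the arrangement count is ≤ 5×10⁵,
  and the χ²(k−1) approximation only beyond that. The exact path matters:
  at n = 6 the χ² approximation misses the exact permutation p by ~0.1.
- **Wilcoxon signed-rank** for post-hoc pairs and the IMPT-vs-IMRT contrast:
  zero differences dropped (all-zero input is flagged and returns p = 1),
  exact two-sided p for n ≤ 25 by convolution over doubled ranks (correct
  under tied |differences|), scipy's tie-corrected normal approximation
  without continuity correction for larger n.
- **Bonferroni** adjustment (min(1, m·p)) over the three pairwise
  comparisons; post-hoc tests are gated on Friedman p < 0.05 by default.
- **Percent-reduction summaries** vs the conventional baseline (median,
  range and mean per-patient percent reduction; zero baselines excluded with
  a warning).

Exactness of both tests is verified against brute-force enumeration oracles
in the suite, and empirical type-I error at the 0.05 level is checked by
simulation.

## 5. Numerical conventions

- **DVH representation.** Cumulative (survival) DVHs on a uniform dose grid
  starting at 0 Gy with 0.01 Gy bins; volume fraction starts at 1 and is
  non-increasing. `Dn%` is the largest dose with survival ≥ n/100, linearly
  interpolated; flat runs resolve to the largest qualifying dose. Mean dose
  is the trapezoidal integral of the survival curve.
- **Delta DVHs.** A uniform dose `D` is represented by a survival curve that
  is 1 up to `D` and 0 one bin later, i.e. a half-bin smear: its trapezoidal
  mean is `D + bin/2` and inverse-CDF samples fall in `(D, D + bin)`. This
  makes sampling means and DVH means agree exactly; all tests state delta
  tolerances as one bin (0.01 Gy).
- **Event-driven transport.** Residence times are consumed in continuous
  seconds, visit by visit, with beam-on overlap computed from the piecewise
  linear cumulative beam-on clock. This is algebraically identical to
  stepping on a fine `dt` grid with fractional-remainder carry, and is what
  makes a 33-fraction, 10⁴-particle course take under a second per plan. The
  literal `step()` kernel is retained for occupancy/relaxation studies and is
  verified against an exact discrete-time Markov-chain oracle.
- **Determinism.** One `numpy.random.Generator` per simulation; the study
  pipeline derives per-plan seeds as SHA-256 of `(study seed, patient,
  condition)` reduced modulo 2³¹, so results are independent of plan
  iteration order and bit-reproducible across reruns. Compartments are
  iterated in fixed order when drawing doses so the random stream is
  consumption-order stable.
- **Serialization.** DVH CSVs are written with 17 significant digits and read
  back with round-trip float parsing, so a serialized cohort reloads
  bit-identically; a manifest of SHA-256 hashes detects corruption and names
  the offending patient/condition.

## 6. Study pipeline and problem sizes

`run_study` (and the `hemodose` CLI) chains cohort generation (or loading),
per-plan simulation, metric extraction, statistics and report writing. The
package's own standard desk-scale configuration — used by
`scripts/acceptance.py` — is 6 patients (5 typical + 1 vessel-overlap
outlier) × 6 conditions at 10⁴ particles: small enough to run in ~30 s,
large enough that the Monte-Carlo standard error of each plan's blood Dmean
is far below the between-patient and between-condition differences being
compared (this separation is asserted by the particle-scaling test). Larger
cohorts (the generator's default is 20 patients) and particle counts scale
linearly in time.

## 7. Limitations

- The compartment tables are plausibility adaptations, not validated
  physiology; absolute blood-dose values should not be read as clinical
  predictions. Relative comparisons (between modalities and constraint
  levels, simulated with common random numbers) are the intended output.
- The dose-rate model assumes each organ's DVH dose is delivered uniformly
  over the beam-on window of every fraction; field-by-field spatial
  sequencing within a fraction is not modeled.
- Blood is assumed well mixed between fractions and compartments are
  well mixed internally; no vascular topology (series connections,
  recirculation loops) is represented.
- The synthetic cohort reproduces the *structure* of a modality/constraint
  comparison, not any particular clinical dataset; its effect sizes follow
  from the generator priors.
- Statistical tests are exact only up to the stated sample-size limits;
  beyond them the documented approximations apply.
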