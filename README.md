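# hemodose

Monte-Carlo estimation of the radiation dose received by circulating blood
during fractionated radiotherapy, with a synthetic-cohort study pipeline for
comparing treatment modalities and blood-vessel-sparing planning constraints.

## The scientific problem

External-beam radiotherapy irradiates not only the static anatomy but also
the blood flowing through the treatment field. Circulating lymphocytes are
exquisitely radiosensitive, and radiation-induced lymphopenia is associated
with worse outcomes in several tumor sites. Unlike an organ, blood is a
moving target: the dose any given blood element accumulates depends on the
interplay between circulation kinetics (how long it dwells in each organ and
how often it returns) and the delivery time structure of the treatment
(fields, fractions, beam-on windows). The quantity of interest is therefore
not a planning-system dose map but the *blood dose–volume histogram* (blood
DVH): the distribution of accumulated dose across the whole blood pool after
a full treatment course.

`hemodose` implements a compartmental blood-flow Monte Carlo in the spirit of
hematological dosimetry frameworks such as HEDOS:

- The circulation is a set of parallel organ compartments with blood volumes
  and blood flows closing on sex-specific whole-body totals
  (male: 5.3 L, 6.5 L/min; female: 3.9 L, 5.9 L/min).
- The blood pool is discretized into computational particles. A particle
  dwells in a compartment for its mean transit time V/Q (or an exponential
  with that mean), then moves to a compartment chosen with probability
  proportional to blood flow. The stationary occupancy of each compartment is
  proportional to its blood volume.
- During the beam-on portion of each fraction, a particle resident in an
  irradiated organ draws a dose level from that organ's planning DVH
  (inverse-CDF sampling) and accrues dose proportionally to the time it
  spends in the organ while the beam is on.
- Per-particle doses accumulated over all fractions are reduced to the blood
  DVH and the summary metrics Dmean, D90%, D70%, D50%, D30%, D10%, D2% and
  V0.9Gy.

On top of the simulator sits a synthetic cohort generator (head-and-neck-like
plans for two modalities — IMRT and IMPT — each planned at three
vessel-sparing constraint levels) and a statistics layer (tie-corrected
Friedman test with exact permutation p-values, exact Wilcoxon signed-rank,
Bonferroni-adjusted post-hoc pairs, percent-reduction summaries) so that the
whole modality/constraint comparison runs as a single reproducible pipeline.

## Running the tests

```bash
python -m pytest -q tests/
```

The suite includes property-based tests (hypothesis), brute-force oracles for
every DVH metric, exact enumeration oracles for the statistics, and an
independent discrete-time Markov-chain oracle for the transport kernel.

## Worked example

Simulate a 33-fraction IMRT course for a toy plan in which the large vessels
receive 50 Gy and the lungs a 5 Gy bath, with all other compartments out of
field:

```python
from dataclasses import replace
import hemodose as hd

# Reference circulation model for a male patient.
ref = hd.build_reference_model("male")
print(f"total blood volume: {ref.total_blood_volume:.1f} L, "
      f"cardiac output: {ref.cardiac_output:.1f} L/min")

# A toy treatment plan: the large vessels get 50 Gy over the course and the
# lungs a 5 Gy low-dose bath; every other compartment is out of field.
in_field = {"large_arteries", "large_veins", "lungs"}
model = hd.CirculationModel(
    sex=ref.sex,
    compartments=[replace(c, in_field=(c.name in in_field))
                  for c in ref.compartments],
    total_blood_volume=ref.total_blood_volume,
    cardiac_output=ref.cardiac_output)

course_dvhs = {
    "large_arteries": hd.CumulativeDVH.delta(50.0),
    "large_veins": hd.CumulativeDVH.delta(50.0),
    "lungs": hd.CumulativeDVH.delta(5.0),
}
schedule = hd.BeamSchedule(modality="IMRT", n_fields=9,
                           field_beam_on=40.0, n_fractions=33)
config = hd.SimulationConfig(n_particles=100_000, seed=7)
result = hd.simulate_course(model, course_dvhs, schedule, config)

for name in ("Dmean", "D90%", "D2%", "V0.9Gy"):
    print(f"{name:>7}: {result.metrics[name]:.4f}")
```

Output:

```text
total blood volume: 5.3 L, cardiac output: 6.5 L/min
  Dmean: 6.5272
   D90%: 5.0755
    D2%: 8.9710
 V0.9Gy: 1.0000
```

Over 33 fractions the blood mixes thoroughly, so every particle visits the
50 Gy vessels many times: the entire blood pool exceeds 0.9 Gy
(V0.9Gy = 1.0) and the blood DVH is comparatively narrow (D90% ≈ 5.1 Gy
vs D2% ≈ 9.0 Gy around a mean of 6.5 Gy).

## Command-line pipeline

```bash
# one-shot study: generate cohort, simulate, analyze, write report bundle
hemodose run-study --patients 6 --particles 10000 --seed 1 --out study_out

# or stage by stage
hemodose generate-cohort --patients 6 --seed 1 --out cohort_dir
hemodose analyze --cohort-dir cohort_dir --particles 10000 --seed 1 --out study_out
hemodose validate-model --sex female
```

`study_out/` will contain tidy CSVs (`metrics.csv`, `target_coverage.csv`,
`blood_metrics.csv`, `reductions.csv`), a human-readable `report.md`,
`statistics.json` (Friedman / Wilcoxon / Bonferroni results) and a
`manifest.json` with the configuration and SHA-256 hashes of every output.
Reruns with the same seed reproduce all outputs bit-identically.

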