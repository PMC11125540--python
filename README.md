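# colosim

A colorectal-cancer natural-history microsimulation with colonoscopy
screening, and a multi-objective search for optimal integer-age screening
schedules.

The model tracks individuals from birth to age 100 in 3-month increments:
adenomas initiate with sex- and age-dependent hazards and an individual
risk multiplier, progress through six stages, and can transform into
preclinical cancer; cancer can also arise directly from normal mucosa
(a fast, hard-to-prevent path with a right-colon preference). Preclinical
cancer progresses through four stages until symptomatic detection; CRC
death is restricted to the first five years after cancer initiation.
Colonoscopy removes detected adenomas (stage-dependent sensitivity,
landmark-by-landmark anatomical reach), can screen-detect preclinical
cancer, may cause (rarely fatal) complications, and triggers guideline
surveillance. Costs are accrued per quarter (screening, polypectomy,
complications, stage- and period-dependent treatment) and discounted at 3%
per year from age 20.

Schedules of 1-4 colonoscopies between ages 20 and 90 (minimum 5-year
spacing) are scored against the paired no-screening arm on four objectives:
CRC mortality reduction, incidence reduction, discounted life-years-lost
reduction, and total cost reduction. Search is exhaustive for 1-2 exams,
and an archive-based mixed-integer metaheuristic with Kung's non-dominated
filter for 3-4 exams.

All inputs are synthetic, packaged fixtures: a Gompertz-Makeham life table
stand-in and disease rates tuned so the no-screening model reproduces
pre-screening-US-like magnitudes (lifetime CRC risk ~5.5%, incidence
peaking around age 80). Bundles serialize to YAML and can be edited or
replaced wholesale.

## Performance design

Cohorts are simulated in two phases: a vectorized presimulation draws every
person's full latent lesion trajectory once, and a compiled replay kernel
applies any screening schedule to those frozen histories. Exam-level
randomness comes from a counter-based hash stream, so all schedules are
evaluated under common random numbers — paired person-for-person with the
no-screening arm — which makes schedule comparisons low-variance and lets a
full 71-point single-exam landscape run in seconds.

## CLI

```bash
colosim simulate --n 100000 --schedule 50,60,70 --out results/
colosim optimize --k 2 --objective dlyl --n 200000 --replicates 3 --seed 7 --out results/
colosim sensitivity --parameter detection --k 1 --out results/
colosim personalize --risk-ratio 2.0 --k 1 --out results/
colosim icer --schedules "55;49,64;44,57,69;40,51,61,72" --out results/
colosim fixtures --out-bundle bundle.yaml --out-benchmarks benchmarks.csv
colosim calibrate --benchmarks benchmarks.csv --out calibrated.yaml
```

Every run writes tidy CSVs, a JSON summary, and a manifest (config hash,
seeds, package version) for byte-exact reruns.

## Package layout

- `colosim.params` — parameter containers (life table, natural history,
  colonoscopy, surveillance guideline, costs) with YAML round-tripping
- `colosim.fixtures` — packaged defaults, benchmark tables, initiation-scale
  calibration
- `colosim.engine` — vectorized presimulation + compiled schedule replay
- `colosim.natural_history` — object-level reference implementation
  (per-person, per-quarter) used by the oracle tests
- `colosim.screening` — schedules, per-exam model, surveillance rules
- `colosim.outcomes` — objectives, life-years accounting, costs, ICERs
- `colosim.optimize` — enumeration, brute force, Kung front, metaheuristic
- `colosim.sensitivity` — one-way scans, bound scenarios, rank-sum test,
  risk stratification
- `colosim.experiment` / `colosim.cli` — config-driven experiment runner
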