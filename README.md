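# metperim

Binocular suprathreshold visual-field screening, hardware-free.

Peripheral visual-field loss is a key safety and efficacy outcome in
retinal clinical trials (gene therapy for choroideremia, treatments for
Stargardt disease), but the standard rapid binocular screen — the
120-point Esterman test — concentrates its locations in the central and
inferior field and places only two above 20° superior, so it badly
under-samples exactly the regions where rod-cone dystrophies lose
vision first. `metperim` implements both the classic Esterman paradigm
and its modified variant (**mET**): 160 locations spread evenly across
the field with two planes of symmetry, extending to 55–60° superiorly,
tested with the larger Goldmann V stimulus.

The package is aimed at vision scientists who need a reproducible,
scriptable implementation of the screening algorithm: it provides the
test grids, the two-pass present/retest engine
(defect ⟺ missed on both presentations, at a fixed 10 dB suprathreshold
level, with interleaved catch trials), simulated observers with
configurable scotomata and response noise, Voronoi-based field maps and
cluster analysis, a four-level severity grading
(normal/mild/moderate/severe), and the agreement statistics used to
compare two tests: weighted κ, Bland–Altman limits of agreement with a
20–80% band filter, and the repeatability coefficient
RC = 1.96·√2·s_w.

The severity rule set, in precedence order: **severe** when ≥ 50% of
locations are missed; **moderate** when there are ≥ 2 adjacency-connected
clusters of ≥ 3 defects; **mild** for any other non-empty defect
pattern; **normal** when no location is defective.

## Worked example

Run the mET against a simulated moderate choroideremia subject (an
absolute scotoma outside a preserved central island), then grade the
logged run:

```bash
$ metperim run --grid met --phenotype choroideremia:moderate --seed 1 --out demo
{"false_positive_rate": 0.0, "files": {"image": "demo/met_seed1_field.png",
 "log": "demo/met_seed1_log.csv", "summary": "demo/met_seed1_summary.csv"},
 "flagged_unreliable": false, "grid": "met", "percent_seen": 26.88, "seed": 1,
 "summary": {"defects": 117, "failed_false_positives": 0,
             "seen_first": 35, "seen_retest": 8}}

$ metperim grade --log demo/met_seed1_log.csv --grid met
{"clusters": [117], "defect_count": 117, "grade": "severe", "percent_seen": 26.88}
```

Reading the output: of the 160 locations, 35 were seen on the first
presentation and 8 more on retest, leaving 117 defects (26.88% seen —
this subject's preserved island covers only the innermost locations).
The 117 defects form one connected peripheral ring, and since
117/160 ≥ 50% the field is graded severe. The catch trials drew no
false-positive responses, so the run is not flagged. The bundle also
contains the per-presentation log CSV
(`order,x_deg,y_deg,goldmann_size,level_db,is_catch,pass,seen`), the
one-row summary CSV, and a Voronoi field map (light grey = seen first,
dark grey = seen on retest, black = defect).

The same machinery is available as a library:

```python
from metperim import (load_grid, make_phenotype, SimulatedResponder,
                      ResponderConfig, run_screening, EngineConfig,
                      voronoi_partition, classify_severity)

grid = load_grid("met")
model = make_phenotype("choroideremia", "moderate", seed=1)
result = run_screening(grid, SimulatedResponder(model, ResponderConfig(seed=1)),
                       EngineConfig(seed=1))
grade = classify_severity(result, voronoi_partition(grid))
print(grade.label, grade.defect_count)   # severe 117
```

Other subcommands: `metperim simulate-cohort` (runs both paradigms over
a seeded synthetic cohort — by default 19 choroideremia, 17 Stargardt
and 26 control subjects — and writes per-subject percent-seen scores
and grades), `metperim compare` (Bland–Altman on paired scores),
`metperim kappa` (weighted κ between two graders) and
`metperim render` (redraw a field map from a log).

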