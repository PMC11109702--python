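# hdssmig

Migration typology of children and adolescents from HDSS (Health and
Demographic Surveillance Site) residence-episode data — built for
demographers and epidemiologists who work with longitudinal surveillance
registers of the Karonga type: persons with parent/spouse links, households
with stable and location-tied IDs plus GPS coordinates, dated residence
episodes with move reasons, and annual survey rounds.

The package turns such a register into an analysis of *who moves, how far,
and with whom*:

1. **Panel** — episodes are reduced to one record per person per quarter
   (snapshot on the 15th of the middle month) with time-varying covariates.
2. **Moves** — a move is a changed geographic household ID at the next
   snapshot, or a recorded boundary crossing; displacements under 5 m are
   dropped as geo-ID reassignment artefacts and at most one move per
   person-quarter is kept (uniformly at random, seeded).  Each move is
   classed **short** (< 4 km) or **long**, and **independent** (no parent of
   any age, no adult ≥ 18 among co-movers) or **accompanied**.
3. **Family** — a kinship graph built from parent and spousal links yields
   the household-composition category (parents & siblings, sister's family,
   …, spouse, external, no IDs), five kin-within-250 m flags and seven
   household age-band counts.
4. **Descriptives** — age–sex risk curves, sending→receiving composition
   flow tables with Sankey JSON export, and moved-with-parents tables, all
   with variances clustered two-way by unique household and individual ID.
5. **Model** — a multilevel multinomial logit of move type (baseline: no
   move) per sex × life stage,

       log P(y = k) / P(y = none) = x′β_k + σ_k a_i ,  a_i ~ N(0, 1),

   with individual random intercepts σ_k a_i (Gauss–Hermite ML) and
   household-clustered robust SEs.

Real HDSS registers cannot be shared, so the package includes a synthetic
register generator (`hdssmig.synthetic`) with the event structure the
analysis assumes — patrilocal marriage migration, divorce return-moves,
child fostering toward maternal kin, household relocations, polygyny,
boundary crossings — and every stage is tested end-to-end against it.
See `docs/methods.md` for the full model description and design choices.

## Worked example

```sh
hdssmig all --outdir run --seed 1
```

runs simulate → panel → moves → family → describe → model on a small
synthetic register and prints

```
wrote 34 files to run (manifest: run/manifest.json)
```

The manifest records a stage-flow table; for seed 1 it reads

```
simulate: 299 persons, 438 episodes
panel:    11375 person-quarters (265 persons)
moves:    176 retained moves — 56 long_independent, 52 short_accompanied,
          51 long_accompanied, 17 short_independent
model_female_child: 1563 rows, 61 individuals  (… one block per stratum)
```

i.e. the generator produced a register in which accompanied childhood
moves (household relocations, divorce returns) and long independent
adolescent moves (marriage migration) dominate — the two mobility peaks
the typology is designed to separate.  `run/moves.csv` holds one row per
retained move with distance, co-movers and the four-way type;
`run/flow_tables.csv` the clustered sending/receiving percentages;
`run/fit_<stratum>.json` the odds ratios and random-intercept variances.

The same objects are available as a library:

```python
from hdssmig import SimConfig, simulate_register
from hdssmig.panel import build_panel
from hdssmig.moves import detect_moves, apply_typology

reg = simulate_register(SimConfig(seed=1, n_founder_households=40))
panel = build_panel(reg)
moves = apply_typology(detect_moves(panel, reg, seed=1), cutoff_km=4.0)
print(moves["move_type"].value_counts())
```

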