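# caretactics

Tactic-based demographic analysis of a hunted brown bear (*Ursus arctos*)
population in which hunting law protects females accompanied by dependent
offspring. Female brown bears wean their litters after either 1.5 or 2.5
years of maternal care; the longer tactic costs reproductive opportunities
(interbirth interval 3 years instead of 2) but keeps the female — and her
yearlings — legally shielded from hunters in 2 of every 3 years instead of
1 of 2. `caretactics` quantifies what that trade-off does to fitness and
population structure:

1. **classify** females into maternal-care tactics from their weaned litters
   and measure the trend, repeatability and correlates of care duration
   (logistic mixed models with a female random intercept);
2. **estimate** tactic- and age-class-specific annual survival
   (S₁, S₂, S₃, S₄₋₈, S₉₊) and recruitment R (yearling daughters per
   female-year) with parametric-bootstrap confidence intervals;
3. **project** each tactic with a 9×9 female-based Leslie matrix
   (fecundities F = S·R on the adult columns, survivals on the subdiagonal,
   a 9+ self-loop) and extract λ (dominant eigenvalue), R₀ (dominant
   eigenvalue of F(I−U)⁻¹), generation time T = ln R₀ / ln λ and the stable
   age distribution, with bootstrap uncertainty propagated through the
   matrices;
4. **evaluate** how the annual hunting-pressure index
   h = shot marked bears / available marked bears shifts each tactic's
   survival and hence λ(h) over a pressure grid.

Because the underlying field data are not publicly deposited, the package
ships a seeded individual-based simulator (`synthetic_population`) that
reproduces the statistical structure the analyses assume — tactic
consistency within females, the family-group protection rule, age-class
survival and recruitment, annual hunting pressure — so every stage is
testable end to end. Intended users: population ecologists and wildlife
managers working with individual-based monitoring data from harvested
populations.

## Worked example

Build the two tactic matrices from the published mean rates and summarize:

```python
from caretactics import build_matrix, summarize
from caretactics.reference import SURVIVAL_MEANS, RECRUITMENT_MEANS

for tactic in ("T15", "T25"):
    s = SURVIVAL_MEANS[tactic]
    m = build_matrix(s["1"], s["2"], s["3"], s["4-8"], s["9+"],
                     RECRUITMENT_MEANS[tactic], tactic=tactic)
    d = summarize(m)
    print(f"{tactic}: lambda={d.lambda_:.3f}  R0={d.R0:.2f}  T={d.T:.2f} y  "
          f"adult share={100*d.adult_fraction:.1f}%")
```

```
T15: lambda=1.093  R0=2.21  T=8.93 y  adult share=57.2%
T25: lambda=1.100  R0=3.14  T=11.97 y  adult share=64.6%
```

Both tactics grow at essentially the same rate (λ ≈ 1.09–1.10): the
2.5-year tactic's survival gain compensates its 35% lower recruitment. The
tactics differ where it matters for management: a 2.5-year-tactic
population turns over ~3 years more slowly (T 11.97 vs 8.93) and holds more
of its stable age structure in adults (64.6% vs 57.2%).

Simulate a population and analyze care-duration tactics:

```python
from caretactics import SimulationConfig, simulate, assign_tactics, weaning_trend, repeatability

cfg = SimulationConfig(n_initial_females=150, n_years=20, seed=42)
bear_years, litters = simulate(cfg)          # 8533 bear-years, 1971 litters
assignments = assign_tactics(litters)        # 661 females, 190 on the 2.5-y tactic
trend = weaning_trend(litters)               # OR 1.21 [1.17, 1.25] per year
rep = repeatability(litters, n_bootstrap=500, seed=1)
# latent-scale repeatability 0.27, original scale 0.14 [0.09, 0.20]
```

The fitted annual odds ratio (1.21) recovers the simulated trend in the
odds of 2.5-year care, and the repeatability estimate reflects the
generator's between-female tactic variance.

The same pipeline runs from the shell:

```sh
caretactics simulate --out data/ --seed 42
caretactics tactics trend --litters data/litters.csv --out trend.json
caretactics rates fit --bear-years data/bear_years.csv --out rates.json --seed 3
caretactics run --config pipeline.yaml     # all stages + manifest
caretactics report --manifest out/manifest.json
```

## Data formats

`bear_years.csv` — one row per monitored female per hunting-season year:

```csv
bear_id,year,age,tactic,status,survived,cause_of_death,available_for_hunting,recruits
F000007,2001,6,T15,solitary,true,none,true,2
F000007,2002,7,T15,with_offspring,false,hunting,false,0
```

`tactic` ∈ {T15, T25, unknown}; `status` ∈ {solitary, with_offspring,
with_mother}; members of family groups always have
`available_for_hunting=false` (a hunting death of a protected female is an
accidental kill). `recruits` counts yearling daughters produced that year
(0–3, empty when not applicable).

`litters.csv` — one row per reproductive event:

```csv
litter_id,mother_id,birth_year,weaning_year,care_duration,litter_size,mother_primiparous
L000012,F000007,1999,2000,1.5,3,false
L000031,F000007,2003,2005,2.5,2,false
L000044,F000019,2004,,lost,2,unknown
```

`care_duration` is 1.5 (weaned the spring after the yearling winter), 2.5
(one extra year in the family group) or `lost` (litter lost before
weaning; no weaning year). Validation on read enforces every invariant
(weaning-year arithmetic, litter sizes 1–4, survival/cause consistency).

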