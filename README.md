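# crtlead

An in-silico trial engine for **quadripolar CRT lead design**.  Cardiac
resynchronization therapy paces the right ventricle (RV) and left
ventricle (LV) together to restore synchronous activation in
dyssynchronous heart failure; multipoint-pacing (MPP) leads carry four LV
electrodes whose placement and programming strongly affect response.
`crtlead` simulates the whole design space on virtual hearts: it builds
synthetic biventricular tetrahedral anatomies (or imports real ones),
computes paced activation with an anisotropic eikonal model, scores
electrical synchrony against an RV-pacing baseline, and selects the
quadripolar designs that serve a whole cohort best.

Intended users: computational cardiac electrophysiologists and
device-design researchers who want a self-contained, deterministic
virtual-trial pipeline with testable numerics.

## Model

Activation times `T` solve the anisotropic eikonal equation

```
sqrt( ∇T · V ∇T ) = 1,    V = cv_f² f fᵀ + (k_xf·cv_f)² (I − f fᵀ)
```

with fibre velocity `cv_f = 0.5 m/s`, cross-fibre ratio `k_xf = 0.6`, an
isotropic fast endocardial conduction layer (`k_fec = 5` times `cv_f`,
one element thick over the apical third of the endocardium) as a Purkinje
surrogate, and an optional scar rule blocking LV elements thinner than
5–6 mm.  Synchrony metrics: **TAT** (total activation time, a QRS
surrogate) and **AT090** (time to activate 90% of the biventricular
myocardial volume, the primary endpoint); benefits are reductions versus
RV-only pacing.  Eight electrode positions (`a` basal … `h` apical,
7.5 mm pitch, 52.5 mm span, start at 80% of the apicobasal distance) in
five epicardial vein tracks (IN, IL, LA, AL, AN — anchored to AHA
segments 4/5…6/1) give 36 stimulus sets per vein; any 4 positions form
one of C(8,4) = 70 lead designs.  Cohort-level selection is an exact
minimum set cover: the fewest designs containing every subject's optimal
configuration.  See `docs/methods.md` for the full account.

## Worked example

```python
from crtlead.pipeline import RunConfiguration, run_pipeline

cfg = RunConfiguration(n_hf=2, n_rr=2, veins=("LA", "AN"),
                       target_edge_length=5.5, seed=1,
                       output_dir="crtlead_output")
summary = run_pipeline(cfg)
print(f"records: {summary['n_records']}")
print(f"mean AT090 reduction: {summary['mean_at090_reduction_pct']:.2f}%")
for cohort, sel in summary["selections"].items():
    print(f"{cohort}: primary design {sel['primary_design']}, "
          f"{len(sel['chosen_designs'])} design(s) cover all optima")
```

prints (deterministically for this configuration):

```
records: 288
mean AT090 reduction: 20.17%
HF: primary design abcd, 1 design(s) cover all optima
RR: primary design abcd, 1 design(s) cover all optima
RR+HF: primary design abcd, 1 design(s) cover all optima
```

288 records are 4 subjects × 2 veins × 36 pacing configurations, each a
full eikonal solve compared against that subject's RV-paced baseline; the
mean AT090 reduction says LV pacing shortened the 90%-activation time by
a fifth on average on these synthetic hearts.  "Primary design abcd"
names the 4-electrode lead (basal positions a–d) containing the largest
number of per-subject optimal configurations; here one design covers all
four subjects' optima.  The same pipeline is scriptable from the shell
(`crtlead run`, `crtlead generate-cohort`, `crtlead place-leads`), and
`run_oat_sensitivity` repeats campaign + selection under one-at-a-time
parameter changes (FEC extent, velocities, anisotropies, RV lead site,
scar thresholds).

Synthetic anatomies reproduce the qualitative structure of real cohorts
(HF hearts larger and slower than reverse-remodelled ones, pacing never
hurting, pairs at least as good as singles) but not published per-patient
activation times; see the limitations section of `docs/methods.md`.

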