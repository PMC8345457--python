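# lagopop

A population-level landscape model of pesticide risk to large herbivorous
mammals (wild rabbit, brown hare), for ecotoxicologists and regulatory risk
assessors who need to move beyond single-substance, single-crop threshold
assessments toward mid-term population-dynamic predictions.

The model couples two components:

1. **An individual-based demographic simulator.** Animals live in "nests" —
   localized groups sharing a circular feeding area — structured into up to
   four age groups, each with a background monthly mortality rate *m_g* and a
   background monthly reproduction rate *r_g* (offspring per reproductive
   female per month) active during a seasonal breeding window. Every day,
   deaths per group are binomial draws at the daily rate
   `1 − (1 − m_g)^(1/30)` allocated uniformly, births are Poisson draws with
   mean `r_g/30` per female, and animals age one day, promoting across group
   thresholds.

2. **A landscape exposure–effects module.** Fields are polygons with inner
   and outer bands and spray schedules. Residues on food items follow
   `C(t) = RUD · rate · drift · 2^(−(t−t_app)/DT50)`, and the daily estimated
   theoretical exposure is `ETE_t = FIR/bw · Σ_items fraction · residue`.
   Regulatory endpoints are turned into clamped linear dose-response
   functions: acute mortality through `(LD0/f, 0)` and `(LD50/f, 0.5)`
   against `ETE_t`; chronic mortality and reproduction through the origin and
   `(LOAEL/f, 0.25)` against a time-weighted average `ETEtwa(t−w, t)` with an
   endpoint-specific window *w*, accepting linearity when the implied effect
   at the adjusted NOAEL lies in 5–10%. Pesticide rates fold into background
   rates assuming independent survival,

   ```
   accumulated mortality = 1 − (1 − m_bg) · Π_x (1 − SR_x)
   final reproduction    = r_bg · Π_x (1 − RE_x)
   ```

   with a one-month lag for chronic mortality (the maximum monthly TWA of the
   previous month) and a two-month span for reproduction.

The bundled case study derives the dose-response lines for two herbicides —
glyphosate (acute `0.000278·ETE_t − 0.055556`, chronic/reproductive
`0.0071·ETEtwa(t−12,t)`) and bromoxynil (acute `0.0313·ETE_t − 0.3125`,
chronic `0.0731·ETEtwa(t−5,t)`, reproduction `0.1·ETEtwa(t−5,t)`) — and runs
them against stable rabbit and hare populations.

## Worked example

Run the bundled dose-grid experiment — four identical rabbit nests (140
individuals, season December–May), one untreated and three treated with
bromoxynil at 0.05 / 0.1 / 0.2 kg/ha fifteen days into the breeding season:

```
$ lagopop simulate bromoxynil_timing_15 --iterations 20 --seed 42 --out out/
bromoxynil_timing_15: 20 iterations x 720 days, 4 nest(s)
  nest_1: final mean abundance 150.7 [138.2, 163.1]
  nest_2: final mean abundance 125.8 [113.9, 137.6]
  nest_3: final mean abundance 108.4 [98.5, 118.3]
  nest_4: final mean abundance 71.2 [62.4, 79.9]
```

Each line is the across-iteration mean total abundance at day 720 (end of the
second annual cycle) with its 95% confidence interval. The untreated nest
returns near its initial 140; abundance after treatment decreases
monotonically with application rate, and the deficit persists into the second
season because the chronic-mortality and reproduction effects act with a
one-to-two-month lag on the breeding window.

Dose-response derivation from raw endpoints:

```
$ lagopop derive-dr endpoints.yaml
glyphosate:
  acute SR = 0.000278*ETE_t -0.055556  (clamped to [0,1])
  chronic = 0.0071*ETEtwa(t-12,t)
    effect at adjusted NOAEL: 7.14% (inside the 5-10% linearity band)
```

Other entry points: `lagopop list-fixtures`, `lagopop validate scenario.yaml`,
`lagopop dump-fixture NAME out.yaml` (write a bundled fixture as an editable
scenario file), and the library API (`lagopop.run`, `lagopop.replicate`,
`lagopop.export`, `lagopop.scenarios`).

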