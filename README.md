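# goutcea

Cost-effectiveness microsimulation of gout treatment strategies: a
one-year, daily-cycle, patient-level Markov model comparing combinations
of urate-lowering therapy (ULT — allopurinol, febuxostat, or none) and
anti-inflammatory flare treatment (naproxen, colchicine, prednisone,
anakinra), with probabilistic sensitivity analysis (PSA), incremental
cost-effectiveness ratios (ICERs), dominance analysis and
cost-effectiveness acceptability curves (CEACs).

It is written for health economists and modellers who want a tested,
scriptable re-implementation of this class of gout decision model — the
published version of which lived in a proprietary TreeAge workbook — plus
the evidence-synthesis layer (Dirichlet transition-matrix estimation,
Bucher adjusted indirect comparison) and synthetic-data generators that
make every stage testable end-to-end without access to patient-level
trial data.

## The model in brief

A newly diagnosed patient enters on day 0 (by default mid-flare), is
assigned once to the on-target branch (serum urate < 0.36 mmol/L, with
ULT-specific probability *p*) or off-target branch, and then faces a
branch-specific daily flare hazard *h*. A flare lasts 7 days, during
which the pain state *s* ∈ {no, mild, moderate, severe pain} evolves
daily under the flare drug's transition matrix **P**. Each day accrues

* utility  *u(s)/365 · (1+0.015)^(−day/365)*, minus an off-target
  disutility (default 0.05/365 per day), and
* cost  *(drug costs + daily other cost c(s)) · (1+0.04)^(−day/365)*.

The PSA draws parameters from the published distributions (outer loop,
default 2,000) and simulates patient cohorts per strategy under common
random numbers (inner loop, default 200). Strategies are ranked by net
monetary benefit *NMB = λ·QALY − cost*; the incremental analysis applies
strict and extended dominance along the efficiency frontier; CEACs report
the probability each strategy maximizes NMB over λ ∈ [0, 80,000] €/QALY.
An exact dynamic-programming oracle (`expected_outcomes_exact`) computes
the cohort expectation at fixed parameters and backstops every simulation
test.

The per-drug pain-transition matrices bundled with the package are
clinically plausible **synthetic stand-ins** (the trial data behind the
originals are not redistributable); provenance is recorded in every run
manifest, and a published naproxen matrix can be dropped in via
`make_paper_fixture(fixtures_dir=...)`.

## Worked example

```python
import numpy as np
from goutcea import (Strategy, make_paper_fixture, sample_parameter_draw,
                     expected_outcomes_exact, run_psa, incremental_analysis)

table, matrices, provenance = make_paper_fixture()
draw = sample_parameter_draw(table, transition_matrices=matrices, psa=False)

for ult in ("no_ult", "allopurinol300", "febuxostat80"):
    e = expected_outcomes_exact(Strategy(ult, "naproxen"), draw)
    print(f"{ult:16s} cost EUR {e.cost:8.2f}   QALY {e.qaly:.5f}   flares/yr {e.expected_flares:.3f}")

psa = run_psa([Strategy(u, "naproxen") for u in ("no_ult", "allopurinol300", "febuxostat80")],
              table, transition_matrices=matrices, n_outer=100, n_inner=100, seed=42)
print(incremental_analysis(psa)[["strategy", "cost", "qaly", "delta_cost",
                                 "delta_qaly", "icer", "label"]]
      .to_string(index=False, float_format=lambda x: f"{x:.4f}"))
```

prints

```
no_ult           cost EUR  7429.08   QALY 0.80173   flares/yr 1.578
allopurinol300   cost EUR  7434.09   QALY 0.82588   flares/yr 1.347
febuxostat80     cost EUR  7748.27   QALY 0.83830   flares/yr 1.303

               strategy      cost   qaly  delta_cost  delta_qaly       icer     label
        no_ult+naproxen 7239.2965 0.7748         NaN         NaN        NaN reference
allopurinol300+naproxen 7248.4454 0.7990      9.1489      0.0241   378.8896      icer
  febuxostat80+naproxen 7565.2691 0.8114    316.8237      0.0124 25582.8854      icer
```

Reading this: at point estimates, no ULT yields the most flares (1.58/yr,
including the entry flare) and the lowest QALYs; ULT trades drug cost for
fewer flares and less time off the serum-urate target. In the 100×100
PSA, allopurinol buys 0.0241 QALYs over no ULT almost for free (its drug
cost is nearly offset by avoided flare costs — hence the small, noisy
ΔC), while febuxostat costs ≈ €317 more for a further 0.0124 QALYs, an
ICER of ≈ €25.6k/QALY — cost-effective only toward the upper Dutch
willingness-to-pay range. Absolute levels depend on the assumed no-flare
daily cost (see `docs/methods.md`); the orderings and ICER magnitudes are
the meaningful outputs.

The same pipeline is scriptable from the shell:

```bash
goutcea run --seed 1 --n-outer 200 --n-inner 200 --out-dir results/base
goutcea scenario --flare-multiplier 5 --seed 1 --out-dir results/severe
goutcea deterministic --out-dir results/point
goutcea ceac --psa results/base/psa_draws.csv --out-dir results/base
```

each writing `psa_draws.csv`, `incremental.csv`, `ceac.csv` and a
`manifest.json` (seed, config hash, matrix provenance); identical
configurations reproduce identical bytes.

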