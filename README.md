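# smo2kinetics

Phase-resolved analysis of skeletal-muscle oxygen saturation (SmO₂) dynamics
in round-based intermittent exercise, built for wearable near-infrared
spectroscopy (NIRS) recordings of boxing-style training: repeated 3-min
rounds separated by 1-min recoveries, with one oximetry sensor per leg and a
chest-strap heart-rate trace, exported as a uniform 1 Hz series.

It is written for exercise physiologists and sport scientists who want the
within-round desaturation and between-round resaturation kinetics of such
sessions as interpretable numbers — delays, rates, durations, heart rates at
the kinetic transitions, per-punch oxygen cost — together with the
group-level inference over athletes, training modalities (heavy bag, pads,
sparring), legs and rounds.

## The model

Within a round, SmO₂(t) is modelled as three line segments: a stable **time
delay** (TD), a **fast desaturation** with rate FDR < 0 over duration DD,
and a lower **equilibrium** where delivery and utilisation balance.  Each
recovery shows the mirror pattern: a **resaturation delay** (RD), a **fast
resaturation** (rate FRR > 0, duration FRD) and a **slow resaturation**.
Candidate breakpoint pairs are searched exhaustively on the 1 s sample grid
(each segment at least 5 s, ordinary least squares per segment, winner by
total SSE, middle segment required to have the strictly steepest slope in
the phase direction), and the reported breakpoints are the continuous
intersection times of adjacent fitted lines,

```
b = (a₂ − a₁) / (s₁ − s₂)        for lines y = a₁ + s₁t and y = a₂ + s₂t.
```

Heart rate at a breakpoint (HRS/HRE within rounds, HRSF/HREF in recovery)
is interpolated from the HR trace at the intersection time.  Residual
variability per phase is the raw median absolute deviation about the fitted
line, robust to the skew of steady-state exercise data.  The fast
desaturation is additionally normalised to work done:
`FDReN = FDR × DD / punches thrown during the fast desaturation`
(% saturation per punch).

Group inference is a balanced within-subject (training × leg × round)
repeated-measures ANOVA per outcome, with adjusted partial eta squared
`adjη²ₚ = df_e(F − 1)/(df_e F + df_err)` (clipped at 0; < 0.01 trivial,
0.01–0.059 small, 0.06–0.137 moderate, ≥ 0.14 large) and Fisher's-LSD-style
paired follow-up contrasts attached to the summary tables.

Because real athlete recordings of this kind are not openly available, the
package ships a seeded simulator (`smo2kinetics.simulate`) that generates
ground-truth-annotated sessions — piecewise-linear SmO₂ kinetics at the
device's 0.5 s update averaged to the 1 Hz export, Gaussian sensor noise,
sparse movement-artifact spikes, rising/partially-recovering heart rate,
and modality-specific Poisson punch trains — so every stage is testable by
parameter recovery.

## Worked example

The `analysis/` drivers run the whole study on a synthetic 10-athlete
cohort:

```
$ python analysis/01_simulate_cohort.py --seed 42
wrote 30 sessions (10 athletes x 3 modalities) to scratch/sessions
  bag: mean punches per round 188.2
  pad: mean punches per round 169.7
  spar: mean punches per round 61.3

$ python analysis/02_fit_phases.py
fitted 660 windows from 10 athletes -> results/fits.csv
  round-1 lead-leg delay (s) by training:
          mean  std
bag       12.2  1.8
pad       11.0  3.2
spar      13.4  2.1

$ python analysis/03_group_stats.py
114 effects tested -> results/effects.csv; 60 significant at 0.05
   outcome   effect      F      p  adj_pes size_class
        TD training   81.5 0.0000     0.89      large
        TD      leg  344.2 0.0000     0.97      large
        TD    round   41.1 0.0000     0.80      large
...
punches_rt training 1537.9 0.0000     0.99      large
```

Sparring throws roughly a third of the punches of bag work at comparable
desaturation kinetics, so its per-punch oxygen cost (FDReN) is several-fold
larger — the punch count is a poor proxy for lower-body muscular load.  The
round effect on TD reflects the delay lengthening across rounds as recovery
between rounds becomes incomplete.  `analysis/04_summary_tables.py` then
formats the per-round exercise/recovery tables (mean ± SD with significance
superscripts) and renders one fitted round with its segment overlays.

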