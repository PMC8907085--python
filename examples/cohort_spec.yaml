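# Annotated cohort specification for `triscreen simulate --spec ...`.
#
# Every continuous variable is described by three numbers -- the median
# and the 2.5th / 97.5th percentiles -- from which the generator
# calibrates a two-piece distribution (split log-normal for markers,
# split normal for demographics).  This example reproduces the packaged
# reference setting: 40 trisomy-21 pregnancies vs 40 euploid controls
# at 11-13+6 weeks.

affected:                 # the trisomy-21 group
  n: 40                   # number of pregnancies to simulate
  age:                    # maternal age, years
    {median: 29.92, p_low: 24.11, p_high: 37.79}
  weight:                 # maternal weight, kg (truncated to 30-150)
    {median: 53.30, p_low: 39.13, p_high: 74.73}
  ga_days:                # gestational age, days (truncated to 77-97)
    {median: 87.00, p_low: 69.10, p_high: 96.98}
  markers:                # MoM-scale marker summaries
    PAPP-A:        {median: 0.37, p_low: 0.04, p_high: 1.65}
    free beta-hCG: {median: 1.76, p_low: 0.15, p_high: 6.95}
    NT:            {median: 1.17, p_low: 0.59, p_high: 2.10}
    AFP-L2:        {median: 1.59, p_low: 0.61, p_high: 3.61}
  label: trisomy21

control:
  n: 40
  age:     {median: 28.44, p_low: 20.35, p_high: 33.86}
  weight:  {median: 50.10, p_low: 42.90, p_high: 63.00}
  ga_days: {median: 89.00, p_low: 80.05, p_high: 97.00}
  markers:
    PAPP-A:        {median: 0.88, p_low: 0.20, p_high: 3.74}
    free beta-hCG: {median: 1.02, p_low: 0.33, p_high: 3.98}
    NT:            {median: 0.87, p_low: 0.59, p_high: 1.15}
    AFP-L2:        {median: 1.00, p_low: 0.39, p_high: 2.12}
  label: control

# Gaussian-copula correlation between the log-MoM marker values, in
# panel order (PAPP-A, free beta-hCG, NT, AFP-L2).  Identity = markers
# independent; any symmetric PSD matrix with unit diagonal is accepted.
correlation:
  - [1.0, 0.0, 0.0, 0.0]
  - [0.0, 1.0, 0.0, 0.0]
  - [0.0, 0.0, 1.0, 0.0]
  - [0.0, 0.0, 0.0, 1.0]

seed: 20211108            # default RNG seed; `--seed` overrides it
family: two_piece         # or `pooled` for a single-sigma log-normal
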