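# reefdesign

Bayesian adaptive design for long-term coral-reef monitoring when the
data show nonlinear trends and sudden disturbance-driven declines.

Monitoring programs that revisit the same reefs for decades eventually
face the question of where the *next* survey effort is best spent —
and whether some sites or reef locations can be dropped without losing
much information about coral health.  `reefdesign` answers this for
site-level hard-coral-cover counts (binomial photo-point data, `y` of
`n = 1250` points per site) from a program of 21 sampling units (7
reef locations × 3 nested sites) surveyed irregularly over two
decades, interrupted by a mass bleaching event.  It is aimed at
quantitative ecologists and biostatisticians running or reviewing such
programs.

## The model and the design criterion

Counts follow a semiparametric binomial mixed model

```
y_srt ~ Binomial(n, pi_srt)
logit(pi_srt) = gamma_sr + beta_t' z_t + beta_d' d_rt + f(x_srt)
                + beta_l BLE98_srt + beta_s Time98_srt
f(x) = beta_0 + beta_1 x + sum_k delta_k |x - eta_k|^3,   K = 3 knots
```

with site-in-reef random intercepts `gamma_sr ~ N(lambda_r, sigma_s²)`,
`lambda_r ~ N(0, sigma_r²)`, whole-of-reef disturbance covariates
`z_t` (bleaching indicator, √cyclone-hours, interaction), per-reef
exposure dummies `d_rt`, a low-rank thin-plate spline `f` of centered
survey time (knots at the k/(K+1) sample quantiles), and interrupted
time-series terms `BLE98` (level change) and `Time98` (slope change)
for the 1998 bleaching event.

The posterior `p(theta, xi | y_h)` — estimated by the built-in
adaptive MCMC and summarized as a Gaussian — becomes the prior for
design.  A candidate design `d` (a subset of the 21 units to visit at
t = 2016.33) is scored by its expected Kullback–Leibler information
gain,

```
U(d) = E_y [ KL( p(theta | y_h, y_d)  ||  p(theta | y_h) ) ],
```

approximated by Monte Carlo (J ≥ 100 rounds of: draw parameters,
simulate next-survey counts via a Taylor-extrapolated mean response,
update by a Laplace approximation, score the closed-form Gaussian
KLD).  Designs are compared through the efficiency
`Eff(d) = U(d) / U(d_L)` against the full 21-unit design `d_L`,
averaged over 20 paired replicates.  Drop-one-reef candidates are
enumerated; the 3⁷ one-site-per-reef space is searched by coordinate
exchange from five random starts.

See `docs/methods.md` for assumptions, approximations, and numerical
details.

## Worked example

Everything below runs on synthetic data generated in-process — no
downloads.  The generator emulates the monitoring program's structure
(7 reefs × 3 sites × 25 surveys over 1994.83–2016.08, n = 1250, a
1998 trend interruption, heterogeneous exposure):

```python
import reefdesign as rd

dataset, truth = rd.generate_dataset(rd.GeneratorConfig(seed=11))
matrices = rd.build_design_matrices(dataset)

samples = rd.fit_mcmc(matrices, priors=rd.PriorSpec(),
                      chains=4, iterations=4000, seed=3)
print(max(v for v in samples.rhat.values() if v == v))
# 1.0139147173691576   (split-chain R-hat, all parameters converged)

prior = rd.summarize_gaussian(samples, scope="all")   # design prior
scenario = rd.make_scenario("a", dataset)             # prevailing conditions

for res in rd.drop_one_reef_efficiencies(scenario, prior, matrices,
                                         J=100, reps=20, seed=21):
    print(f"omit {res.design.label}: {100 * res.mean:.2f}% "
          f"(sd {100 * res.sd:.2f})")
# omit SL1: 87.83% (sd 4.70)
# omit SL2: 87.26% (sd 4.65)
# omit SL3: 89.17% (sd 4.40)
# omit SL4: 88.78% (sd 4.20)
# omit SS1: 86.50% (sd 5.51)
# omit SS2: 85.97% (sd 4.90)
# omit SS3: 90.89% (sd 3.08)
```

Reading the output: omitting any one reef location retains ~86–91% of
the expected information of the full design, and the seven candidates
are within a few points of each other (differences comparable to the
replicate spread) — no reef location is special, so the choice of
which to drop is essentially inconsequential in this synthetic
program.  The same conclusion holds
under the widespread-disturbance scenario (`make_scenario("b", ...)`),
at slightly higher efficiencies.

The command-line interface wraps the same workflow:

```
reefdesign simulate --seed 11 --out data/
reefdesign fit --data data/ --chains 4 --iterations 4000 --seed 3 --out posterior/
reefdesign design --data data/ --prior posterior/design_prior.json \
                  --objective drop-reef --scenario a -J 100 --reps 20 \
                  --seed 21 --out design/
reefdesign efficiency --data data/ --prior posterior/design_prior.json \
                      --design "SL1:2,SL2:1,SL3:2,SL4:1,SS1:1,SS2:1,SS3:1" \
                      --scenario a --out eff.json
```

All outputs embed the seeds and a configuration hash for exact replay.

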