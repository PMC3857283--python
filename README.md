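# camsecr

Bayesian spatially explicit capture–recapture (SECR) for camera-trap
surveys of individually identifiable animals, with prey relative-abundance
indices from the same photo stream.

Camera-trap studies of patterned carnivores (leopards, tigers, jaguars)
identify individuals from their coat patterns and ask a deceptively simple
question: **how many animals per unit area?** Classical capture–recapture
gives an abundance `N` but needs an ad-hoc "effective survey area" to turn
it into a density. SECR removes that step by modelling *where* each animal
lives: every individual has a latent activity centre `s`, and the chance of
being photographed at a trap declines with the distance between the centre
and the trap.

## The model

Let `y[i,j,k] ∈ {0,1}` record whether individual `i` was photographed at
trap `j` on nightly occasion `k`. The population is embedded in an
augmented super-population of size `M = n + naug`; each member carries an
inclusion indicator `z_i ~ Bernoulli(ψ)` and an activity centre `s_i`
uniform over the suitable points of a discretised state space (the trap
rectangle plus a generous buffer, meshed at regular spacing, with
unsuitable habitat masked out). Detection follows a half-normal encounter
rate with a trap-specific behavioural response (model "Mb"):

    λ_ijk = λ0 · exp( −d(s_i, x_j)² / (2σ²) ) · exp( b1 · C[i,j,k] )
    y[i,j,k] | z_i = 1  ~  Bernoulli( 1 − exp(−λ_ijk) )

where `C[i,j,k] = 1` once `i` has been caught in trap `j` before occasion
`k`. Realised abundance is `Ns = Σ z_i` and density `D = Ns / (suitable
area) × 100` (animals per 100 km²). The posterior is sampled by
Metropolis-within-Gibbs: exact full conditionals for `z` and `ψ`, mesh
moves for the centres, random-walk Metropolis for `(log λ0, log σ, b1)`.
Convergence is checked with Geweke z-scores (|z| > 1.6 flagged) and model
adequacy with a posterior predictive Bayesian p-value using a
Freeman–Tukey discrepancy on individual × trap encounter frequencies.

Because raw survey data of this kind are rarely public, the package ships
a first-class synthetic-data module that emulates the canonical montane
leopard design — 13 paired camera stations over ~31 km² (nearest-neighbour
spacing 1.7–3.5 km), 63 nightly occasions, 819 trap nights — so every
stage of the pipeline is testable end to end, including parameter recovery
at realistic operating points.

## Worked example

Simulate a survey at the canonical design and fit it with a reduced MCMC
profile (a 2 km mesh and 25,000 iterations; the paper-scale profile is a
1 km mesh and 100,000 iterations with 20,000 burn-in):

```bash
camsecr simulate --out demo --seed 1 --spacing 2
camsecr fit --captures demo/captures.csv --deployment demo/deployment.csv \
            --statespace demo/statespace.csv \
            --iterations 25000 --burnin 5000 --seed 7 --pvalue --out demo_fit
```

which prints (plus a `Bayesian p-value: 0.430` line in the log):

```
               mean         sd   hpd_lower   hpd_upper  geweke_z
D         12.487194   2.581563    8.041958   17.001748  0.451087
lambda0    0.022447   0.010605    0.004873    0.043138  1.751584
sigma      1.611389   0.333522    1.098907    2.295974 -1.669221
b1         0.972014   0.490406    0.011040    1.953232 -1.769380
psi        0.733134   0.152416    0.467663    0.997934  0.436012
Ns       285.707000  59.066153  183.000000  388.000000  0.451087
```

The survey was simulated with true density 10.73 per 100 km², λ0 = 0.029,
σ = 1.69 km and b1 = 1.10: the posterior mean density (12.5, SD 2.6)
covers the truth, σ and b1 are recovered within one posterior SD, and the
p-value of 0.43 shows no evidence of misfit. The marginal Geweke flags
(|z| slightly above 1.6 for the detection parameters) are typical of this
deliberately short chain; the run log recommends the full profile when
they appear. Other subcommands: `design-check` (station spacing and
coverage rules), `buffer-scan` (density across buffer widths with and
without a habitat mask), `rai` (independent photographic events per 100
camera days and days-to-first-photo index per species), `summarize` and
`diagnose` for post-processing saved chains.

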