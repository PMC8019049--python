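# famcr — multievent capture–recapture for family units

`famcr` estimates demographic parameters for species with **extended
parental care** — long-lived mammals (polar bears, great apes,
elephants) whose dependent young stay with the mother for more than one
breeding season. Standard capture–recapture models assume independent
individual encounter histories; that assumption breaks when a cub's
survival is conditioned on its mother's, and when a mother seen alone
may either have lost her litter or already have seen it off to
independence. `famcr` treats the **family unit** (mother plus dependent
offspring) as the statistical unit and fits a multievent (hidden
Markov) model to family encounter histories.

It is aimed at quantitative wildlife ecologists: it simulates encounter
histories under configurable study designs, fits by maximum likelihood
or MCMC under parameter-sharing constraints, and derives litter
survival and multi-year reproductive outcomes.

## The model

Twelve demographic states S (independent juveniles/subadults J2–SA5,
mothers with one/two cubs A01/A02 or yearlings A11/A12, successful
breeders with departing two-year-olds AS1/AS2, lone adults A, dead D)
evolve by the annual transition

```
Ψ = Φ · Ψ1 · Ψ2 · Ψ3
```

where Φ (12×12) is survival of the independent female (φ), Ψ1 (12×13)
is dependent-offspring survival conditional on the mother surviving
(s1, s2 cub survival in singleton/twin litters; s3, s4 the yearling
analogues; κ the probability of first reproduction at age 5), Ψ2
(13×16) is the breeding decision conditional on the last reproductive
outcome (β1–β4), and Ψ3 (16×12) is litter size for breeders (γ1–γ4,
the singleton probability). The observation process factors as
`E = E1(d) · E2`: E1 maps states to what could be seen at capture date
d — a two-year-old has already departed with probability α(d), constant
or increasing logistically over the spring field season — and E2
applies class-specific detection p. The likelihood of a family history
is computed by the forward algorithm, conditioned on first capture,
with the initial state mixture π estimated on the simplex.

Derived quantities: litter survival `l02 = 1 − (1 − s2)²` (twin cubs),
`l12 = 1 − (1 − s4)²` (twin yearlings), and the probability that a lone
female raises 0/1/2 offspring to independence within three years,
e.g. `Pr(X=2) = φ³·β3·(1−γ3)·s2²·s4²`.

## Worked example

Simulate the high-detection, constant-departure scenario (T = 15
occasions, 80 newly marked family units per occasion, detection 0.7,
departure rate 0.5) and refit it:

```python
import numpy as np, famcr

cfg = famcr.scenario("S3")
data = famcr.simulate_dataset(cfg, np.random.default_rng(7))
model = famcr.FamilyUnitModel(
    data,
    constraints=famcr.scenario_constraints("constant"),
    template=cfg.true_params,
)
res = model.fit(starts=2, seed=0)
print(res.summary())
```

```
Family-unit multievent model (MLE)
families: 1200   occasions: 15   free parameters: 25
log-likelihood: -10596.436   converged: True
                                               parameter  estimate     se   lo95   hi95
phi1=phi2=phi3=phi4=phi5=phi6=phi7=phi8=phi9=phi10=phi11    0.8914 0.0046 0.8821 0.9000
                                                      s1    0.5916 0.0198 0.5523 0.6298
                                                      s2    0.5913 0.0162 0.5593 0.6226
                                                      s3    0.7681 0.1009 0.5218 0.9095
                                                      s4    0.6153 0.1074 0.3965 0.7956
                                                   beta1    0.4898 0.0274 0.4365 0.5434
                                                   beta2    0.5271 0.2406 0.1439 0.8808
                                                   ...
                      p1=p2=p3=p4=p5=p6=p7=p8=p9=p10=p11    0.6930 0.0075 0.6782 0.7075
                                                  alpha0    0.4630 0.0793 0.3157 0.6170
```

The shared survival estimate 0.891 (SE 0.005) and shared detection
0.693 (SE 0.008) recover the generating values 0.9 and 0.7; the wide
interval on β2 (breeding after losing a yearling litter) reflects how
rarely that history is observed — the weakly identified corner of this
design. Derived quantities from the same fit:

```python
ls = res.litter_survival()          # l02=0.8330, l12=0.8520
out = res.three_year_outcomes()     # pr0=0.6504, pr1=0.3126, pr2=0.0370
```

i.e. a lone female has a 3.7% chance of raising two offspring to
independence within three years under these estimates.

The same workflow is available from the shell:

```sh
famcr simulate --scenario S2 --seed 7 --out d.csv
famcr fit d.csv --preset scenario_seasonal --out fit.tsv
famcr project fit.tsv
famcr evaluate --scenario S2 --reps 20 --seed 1
famcr validate mydata.csv
```

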