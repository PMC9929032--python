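# bouncebayes

A Bayesian observer model of how rugby players anticipate the bounce of
an oval ball, with tools to estimate each observer's reliance on sensory
cues versus prior beliefs from their categorical responses.

## The problem

When an oval rugby ball is kicked along the ground it can roll on or
suddenly rear up, and players must commit to "high" or "low" before the
bounce resolves. In a temporal-occlusion anticipation test, observers
watch kick clips cut off at one of three points — postural cues only
(PC), ball flight only (BF), or both (PC&BF) — and predict the bounce
height. The question is how much each observer weights the online
sensory cue against their prior expectation about bounciness, and
whether that weighting differs between professional players and novices.

## The model

Each trial is a two-timestep POMDP. The observer starts in a `start`
state (initial-state vector **D** = (1, 0, 0)) and transitions to a
hidden `high` or `low` bounce state under the transition matrix

```
        start  high  low
start |   0     0     0 |
high  | 1-pB    1     0 |      pB = prior probability of a low bounce
low   |  pB     0     1 |
```

At *t* = 2 the observer receives a cue whose reliability is the sensory
precision SP through the likelihood matrix

```
           start  high   low
start_obs |  1     0      0   |
high_cue  |  0     SP    1-SP |   SP = P(cue matches the bounce state)
low_cue   |  0    1-SP    SP  |
```

Belief updating is a softmax over summed log-messages
(s̄₁ = σ(½(ln D + ln Bᵀs̄₂) + ln Aᵀo₁), s̄₂ = σ(ln B s̄₁ + ln Aᵀo₂)),
which for this model reduces to Bayes' rule over the two bounce states:

P(high | high cue) = (1−pB)·SP / [(1−pB)·SP + pB·(1−SP)].

Responses follow probability matching: P(respond "high") equals the
posterior over the high state. Given an observer's trial-level
responses, (SP, pB) are estimated by MAP on the logit scale with a
Gaussian shrinkage prior (mean logit 0.5 = 0, precision 1/2), per
participant overall and per kick-type × occlusion cell.

## Worked example

```python
from bouncebayes import ModelParams, response_probability

p = ModelParams(SP=0.8, pB=0.6)
print(response_probability(p, "high_cue"))   # 0.7272727272727273
print(response_probability(p, "low_cue"))    # 0.14285714285714285
```

An observer with a fairly reliable cue (SP = 0.8) but a prior leaning
toward low bounces (pB = 0.6) responds "high" on ~73% of trials showing
a high-bounce cue, and ~14% of trials showing a low-bounce cue — the cue
dominates but the prior still drags both probabilities toward "low".

The full pipeline runs from the command line or the numbered scripts in
`analysis/`:

```bash
bouncebayes all --seed 0 --out-dir results
# or equivalently
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_fit_participants.py --seed 0
python analysis/03_parameter_recovery.py --seed 0
python analysis/04_screen_and_summarize.py
```

With the default settings this simulates the study cohort (38 experts,
20 novices, 111 trials each), fits every participant, and prints, e.g.:

```
fitted 58 participants (406 fits, 406 converged)
group means (overall fits):
        SP_hat  pB_hat
expert   0.750   0.441
novice   0.631   0.463
```

i.e. simulated experts (generated with higher cue sensitivity) are
recovered with clearly higher SP than novices, while both groups sit
near indifference (0.5) in their bounce priors. The recovery stage
reports how well known parameters are re-estimated:

```
recovery over 100 simulated responders (0 non-converged, excluded):
  SP: r^2 = 0.919
  pB: r^2 = 0.918
```

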