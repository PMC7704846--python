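# dutchpt

A dynamic prospect-theory model of competitive bidding in descending-price
(Dutch) auctions, plus the analysis pipeline that goes with it.

In a Dutch auction the price falls from a random start toward $0 and the
first bidder wins at the current clock price. The model treats each of three
concurrent players as making a bid/wait decision at every clock step:

- **utility** of a prospect is the standard two-branch power form
  (gain exponent α, loss exponent β, loss aversion λ);
- the risk that a competitor bids in the next window, derived from a
  truncated-normal belief N(μ, σ) over opponent bid times, is filtered
  through an **inverse-S probability weighting function** (exponents γ/δ);
- the two weighted utilities are converted to a per-step bid probability by
  a **softmax** rule with sensitivity c.

The per-step probabilities form a discrete-time hazard, which is converted
to a bid-time density/CDF and composed across the three players through the
minimum-order-statistic CDF `1 − (1 − G)³`. Monte-Carlo simulation produces
winning-bid records; the stats layer supplies Pearson correlations,
low/high start-price bin comparisons (pooled-variance t), paired condition
comparisons with a normality pre-check, and default JZS Bayes factors
(Cauchy prior, scale √2/2) computed by numerical integration in log space.

A synthetic-data module emulates the experimental platform's trial logs
(11 three-person groups × 2 step-rate conditions × practice + 5 blocks × 12
trials, uniform $50–$150 start prices, fixed or variable unit quantities,
per-block budget/warehouse bookkeeping) so the full analysis pipeline runs
without any external download.

## Layout

| module | contents |
|---|---|
| `dutchpt.auction_env` | price clock, start-price/unit sampling, experiment design, step normalisation |
| `dutchpt.prospect_agent` | utility, probability weighting, competitor hazard, softmax bid probability |
| `dutchpt.group_simulator` | hazard→density/CDF transforms, group-minimum CDF, auction Monte-Carlo |
| `dutchpt.stats` | correlations, bin splits, pooled t, JZS Bayes factors, paired tests, ECDF |
| `dutchpt.synthetic_data` | trial-log generation, CSV dialect read/write, manifests |
| `dutchpt.config` / `dutchpt.cli` | YAML config handling and the `dutchpt` command |

## CLI

```sh
# simulate group auctions under a config (or the built-in fitted parameters)
dutchpt simulate --n 1000 --seed 1 --condition discrete --out sim.csv

# generate a synthetic experiment trial log (1 = fixed units, 2 = variable)
dutchpt generate --experiment 1 --seed 1 --out trials.csv

# run the analysis battery on a trial log
dutchpt analyze --in trials.csv --report report.json

# re-run the published model-simulation study (both conditions, n=1000)
dutchpt reproduce-model --seed 1 --out model_report.json

# synthetic end-to-end reproduction of both experiments
dutchpt reproduce-synthetic --seed 1 --outdir synthetic_out

dutchpt config-check cfg.yaml   # validate + echo a YAML config
```

Example YAML config:

```yaml
dt_s: 0.5
start_price_low: 80
start_price_high: 120
alpha: 0.88
beta: 0.88
lambda: 2.25
gamma: 0.61
delta: 0.69
c: 0.3
V: 1.43
mu: 2.01
sigma: 0.97
```

Every artefact-producing command writes a sidecar `*.manifest.json` with the
seed, config hash and package version, so runs are replayable.

## Modelling notes

Two typographic defects in the source equations are corrected by default
(both switchable for audit): the weighting function uses the canonical
two-parameter form `p^e / (p^e + (1−p)^e)^(1/e)`, and the softmax exponent
is positive so that higher weighted utility means higher choice
probability. The perceived value of the goods is anchored to the start
price (`P = V·C(0)`); the alternative current-price anchor
(`value_anchor: current_price`) is implemented but produces qualitatively
different (and empirically wrong-signed) start-price effects.
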