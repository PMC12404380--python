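# spamodel

Tools for diagnosing **spurious prospective associations** in two-wave panel
data, built around the **SPAM** (Spurious Prospective Associations Model): a
trait-state structural equation model that reproduces observed cross-lagged
regression effects between two constructs *without any causal path between
them*.

## The problem

Longitudinal studies (and meta-analyses of them) routinely report that
construct X at time 1 predicts construct Y at time 2 after adjusting for Y at
time 1, and read this cross-lagged effect as evidence of a prospective causal
influence.  But the adjusted effect is a pure function of correlations,

&emsp; E(β<sub>x1,y2·y1</sub>) = (r<sub>x1,y2</sub> − r<sub>x1,y1</sub>·r<sub>y1,y2</sub>) / (1 − r<sub>x1,y1</sub>²),

and correlations with residuals plus regression to the mean can make it
nonzero with no causal effect at all.  Three companion effects complete a
diagnostic battery:

* the **time-reversed** adjusted effect, β<sub>x1,y1·y2</sub> — a genuine
  prospective effect flips its sign relative to the forward effect; a
  spurious one preserves it;
* the effect of X1 on the **change score** Y2 − Y1,
  (r<sub>x1,y2</sub> − r<sub>x1,y1</sub>) / √(2(1 − r<sub>y1,y2</sub>)) — positive
  under a true increasing effect, zero or opposite-signed under spuriousness;
* the **change-on-change** effect of X2 − X1 on Y2 − Y1,
  (r<sub>x1,y1</sub> + r<sub>x2,y2</sub> − r<sub>x1,y2</sub> − r<sub>x2,y1</sub>) /
  √(4(1 − r<sub>x1,x2</sub>)(1 − r<sub>y1,y2</sub>)).

The SPAM generates all six correlations from four parameters: a shared trait
loading **a** (sign s = ±1 for positively/negatively associated pairs), two
stability loadings **b** and **c**, and an occasion-specific state covariance
**d**:

    r(X1,X2) = b²    r(Y1,Y2) = c²
    cross-lagged  r = s·a²·b·c
    concurrent    r = s·a²·b·c + d

The package fits this model by normal-theory maximum likelihood to any
4×4 correlation matrix, reports χ², CFI, TLI and RMSEA, simulates data
(exactly or stochastically), pools per-study correlations and effects by
random-effects meta-analysis on the Fisher-z scale (REML or
DerSimonian–Laird), and runs the full six-step evaluation pipeline:
simulate at the pooled correlations → fit the SPAM → simulate from the
fitted structure → re-estimate the four effects → compare against the
observed ones and classify the sign pattern.

Intended users: epidemiologists, psychologists and biostatisticians who work
with two-wave observational data or meta-analyze cross-lagged effects, and
want to check whether a claimed prospective effect survives the sign-pattern
diagnostic.

## Worked example

Pooled correlations between loneliness (X) and social anxiety (Y) measured
at two occasions, in the order r_x1x2, r_x1y1, r_x1y2, r_x2y1, r_x2y2,
r_y1y2:

```python
from spamodel import CorrelationSet, effects_bundle, fit_spam

cs = CorrelationSet(0.603, 0.493, 0.379, 0.351, 0.552, 0.568)
print([round(v, 4) for v in effects_bundle(cs).xy.as_tuple()])
# [0.1308, 0.3243, -0.1226, 0.3803]
```

The forward adjusted effect (+0.131) looks like loneliness raising later
social anxiety — but the time-reversed effect (+0.324) is *also* positive
(a genuine increasing effect would make it negative), the change effect is
negative (−0.123), and the change-on-change effect opposes it (+0.380):
exactly the pattern regression-to-the-mean artifacts produce.

The same verdict from the end-to-end pipeline, on the command line:

```console
$ spamodel evaluate --pair loneliness-social_anxiety --seed 1
SPAM evaluation (n=10000, exact=True, seed=1)
  fitted: a1=0.790 a2=0.790 b=0.777 c=0.755 d=0.158 chi2=28.10 (df=6) CFI=0.998 TLI=0.998 RMSEA=0.019
  xy: lagged fwd +0.1308 -> predicted +0.0933; verdict spurious-positive
  yx: lagged fwd +0.0710 -> predicted +0.0690; verdict spurious-positive
```

A SPAM with a strong shared trait (a = 0.79), high stabilities
(b = 0.78, c = 0.76) and a modest state covariance (d = 0.16) fits the
pooled structure almost perfectly (RMSEA 0.019) and predicts cross-lagged
effects (+0.093, +0.069) inside the meta-analytic 95% confidence intervals
of the observed ones — prospective associations of this size need no causal
path.

Other subcommands: `effects`, `fit`, `simulate`, `meta`, `analyze`
(raw two-wave CSV with columns X1, X2, Y1, Y2); see `spamodel --help`.

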