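# specscreen

Spectrum-effect relationship screening for herbal-medicine fingerprints:
which chromatographic peaks in a multi-herb preparation track its measured
pharmacological effect?

The package was built around a two-herb decoction study (*Scutellaria
baicalensis* root + *Gardenia jasminoides* fruit, four raw/processed
combinations, an acute-lung-injury rat model) and ships the study's
published tables as fixtures, but every stage is generic: it takes any
peaks × observations area table and any groups × indicators efficacy panel.

## What it computes

1. **Pharmacodynamic preprocessing** — weighted histology lung-injury score
   (20A + 14B + 7C + 7D + 2E per field, /100), inhibition-rate positive
   transformation `(model − treatment)/model × 100`, replicate RSD.
2. **Composite efficacy rating** — analytic hierarchy process weights
   (principal eigenvector of a reciprocal comparison matrix, Saaty CR
   check), entropy weights (information divergence across groups), their
   combination, and the weighted composite score per formulation.
3. **Three correlation engines** per indicator over z-scored peak rows:
   - Pearson `r` with t-based p-values, ranked by |r| (top-k rule);
   - grey relational analysis: `ε_i(k) = (Δmin + ρΔmax)/(Δ_oi(k) + ρΔmax)`
     with global extremes and ρ = 0.5, screened at GRD > 0.8;
   - from-scratch NIPALS OPLS (one predictive + n orthogonal components,
     Trygg–Wold filtering), VIP ≥ 1 screening, k-fold Q², permutation test,
     OPLS-DA and NIPALS PCA for overviews.
4. **Consensus + network prioritization** — per-indicator three-way
   intersection, deduplicated union, a typed herb–compound–indicator graph
   (degree = indicator memberships + 1 herb edge; betweenness; closeness),
   and a strict-above-median centrality filter (2-of-3 rule).
5. **Synthetic benchmark** — log-normal peak areas with replicate noise and
   indicators that are noisy linear combinations of planted active peaks,
   plus sensitivity/precision scoring of any screened list.

## Worked example

```python
from specscreen import WeightScheme, composite_score, load_fixture

panel = load_fixture("table6")            # positively transformed indicators
weights = WeightScheme(load_fixture("weights"))
print(composite_score(panel, weights).round(2))
```

```
PW4    51.46
PW3    48.24
PW2    47.17
PW1    43.35
```

The composite score is the weight-blended percent improvement over the
untreated model group; the ordering identifies the wine-processed-root +
processed-fruit combination (PW4) as the most effective variant.  Screening
the 57-peak fingerprint against the lung-injury score
(`examples/02_three_method_screen.py`) ranks oroxylin A (A40) and oroxylin A
7-O-glucuronide (A27) first by both |r| (0.93, 0.88) and grey relational
degree (0.85, 0.80), and their three-way consensus `['A27', 'A40']` matches
the leading members of the published consensus set for that indicator.  The
network stage (`examples/03_network_prioritization.py`) reproduces all 20
published compound degrees and flags
`A7, A11, A18, A27, A32, A40, B11, B16` as the centrally placed candidates.

More narrative walkthroughs live in `examples/`; a thin CLI (`specscreen
run-all --simulate …`, `specscreen score`, `specscreen network …`) wraps the
same library calls.

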