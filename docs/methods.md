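# Methods

## Problem setting

A spectrum-effect relationship study asks which constituents of a complex
preparation drive its measured effect.  The data are (a) a fingerprint table
of characteristic chromatographic peak areas across formulations (here 57
peaks, A1–A40 at 254 nm and B1–B17 at 440 nm, over four raw/processed herb
combinations PW1–PW4), and (b) a panel of pharmacodynamic indicators per
formulation group (lung wet/dry ratio, histology injury score, BALF
neutrophils and protein, TNF-α, IL-6, IL-1β).  Because the published
fingerprint is a group-mean table, the correlation stages run on sequences
of at most four points; all conclusions at that scale are rankings, not
significance claims, and the package treats them as such (p-values are
reported descriptively, without multiplicity correction).

## Preprocessing

Indicators are re-oriented so larger = better via the inhibition rate
`(model − treatment)/model × 100`, applied uniformly to all indicators (the
source tables print positively transformed values for all seven, so the
packaged panel is used as-is and the transformation is available for raw
panels).  Peak rows are z-scored with the n−1 denominator (the SPSS
"save standardized values" convention); constant rows map to zero with a
warning rather than an error, since an uninformative peak should not abort
a screen.

## Composite efficacy rating

AHP weights are the normalized principal right eigenvector of a positive
reciprocal pairwise-comparison matrix, computed by power iteration
(tolerance 1e−12, ≤10⁴ iterations) and cross-checked against a dense
eigendecomposition in the tests.  The consistency ratio is
`[(λmax − n)/(n − 1)]/RI(n)` with Saaty's random index; CR ≥ 0.1 logs a
warning.  Entropy (EWM) weights min-max normalize each indicator across
groups, convert to shares, and weight by divergence `1 − e_j`; a constant
indicator has zero divergence and hence zero weight.  The two schemes merge
multiplicatively (`w ∝ a·b`, renormalized) by default — note this sharpens
non-uniform weights, so only the uniform scheme is a fixed point — or by
arithmetic mean.  Because the exact combination used to produce the
published seven weights is not reconstructible, those weights ship as a
fixture and the composite score never depends on the combiner: it is the
plain weighted sum of positively oriented indicator values, with no further
rescaling.  Applied to the packaged panel it reproduces all four published
overall ratings within ±0.01.

## The three screens

**Pearson.** Per-peak correlation with the indicator, p from
`t = r√((n−2)/(1−r²))` on t(n−2).  Ranking is by |r| with ties broken by
peak id; an inversely tracking constituent is as informative for screening
as a direct tracker, and a signed ranking remains available.  Top-5 is the
default selection.

**Grey relational analysis.** Deng formulation:
`ε_i(k) = (Δmin + ρΔmax)/(Δ_oi(k) + ρΔmax)` with Δ extremes taken globally
over all subsequences of one parent and ρ = 0.5; the grey relational degree
is the mean coefficient, screened at GRD > 0.8, top-10.  Sequences are used
as supplied; classic per-sequence normalizations (min-max, mean-image,
initial-value) sit behind a flag.  Within the pipeline the parent indicator
is z-scored to match the z-scored peak subsequences.  This is deliberate:
grey coefficients depend on absolute differences, so parent and
subsequences must be commensurate — feeding a percent-scale parent against
z-scored peaks collapses every GRD into a narrow band determined by the
parent's magnitude, making the 0.8 threshold meaningless.

**OPLS/VIP.** A from-scratch NIPALS implementation.  PLS1:
`w = X'y/‖X'y‖`, `t = Xw`, `p = X't/(t't)`, `q = y't/(t't)`, deflate,
repeat.  OPLS (single y): `w` is fixed once from the original X; each
orthogonal round computes the current loading `p`, removes the direction
`w_o ∝ p − (w'p)w`, and deflates X by `t_o p_o'`; the final predictive
component is fitted on the filtered X.  With no orthogonal components the
model is exactly one-component PLS1 (asserted to 1e−10).  X is centered and
unit-variance scaled by default, y centered.  The default model shape for
single-indicator fits is one predictive + one orthogonal component, with
early stop when `‖w_o‖` vanishes.  VIP uses
`VIP_j = √(p·Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a)` over predictive
components (mean VIP² = 1 by construction); a "total" mode adds orthogonal
components weighted by their explained X-variation.  Q² = 1 − PRESS/SS_tot
from k-fold deleted predictions, venetian-blind fold assignment, default 7
folds reduced to leave-one-out when n < 7 — so four-group fits are LOO.
The permutation test refits under label permutations (default 200) and
reports the permuted R²Y/Q² distributions and exceedance count, seeded and
bit-reproducible.

## Consensus and network

A peak survives an indicator when it passes all three screens; the per-
indicator intersections are unioned (composite-rating pseudo-indicator
included) and deduplicated.  The tripartite graph links each compound to the
indicators it serves and to its single source herb, so compound degree =
indicator count + 1.  Built from the published consensus sets, the graph
reproduces all 20 published compound degrees exactly.  Betweenness is
normalized shortest-path betweenness; closeness is reachable-nodes over
summed distances within the component (the Cytoscape convention).  Published
betweenness/closeness decimals are compared diagnostically only — they
depend on graph details (herb attachments, possible extra nodes) the source
tables do not fully pin down; the source chemistry and network tables even
disagree on a few compounds' herb of origin (e.g. A6, A7, A9, A18, A27,
A34), so both maps ship, with the chemistry table's as default.  Degree is
invariant to that choice.

The median filter flags a compound when at least 2 of its 3 centralities
lie strictly above the compound-wise medians.  The 2-of-3 rule is the
package default because it exactly reproduces the published flag set
(including a degree-2 compound that a strict 3-of-3 reading would exclude);
the required count is configurable, and flags are monotone in it.

## Synthetic data generator

Emulates the structure, not the chemistry, of a fingerprint study:
group-level peak means iid log-normal (defaults: log-mean 10, log-sd 0.5,
matching the positive right-skewed scale of real area tables), replicates
log-normal around group means at 10 % CV (the magnitude of the published
SD/mean ratios), and each indicator
`offset + scale·(Σ_active β_j z_gj + ε)` with z the per-peak standardized
group means, β = +1 per active by default, ε ~ N(0, 0.25), and
offset/scale 50/10 mapping onto a percent-like inhibition-rate scale.
Defaults: 12 groups × 6 replicates, 50 peaks, 5 actives, 7 indicators.
What it does not emulate: chromatographic drift, co-elution, detector
response factors, inter-peak abundance correlations, or indicators with
distinct mechanistic drivers — all indicators share one latent effect, so
passing recovery tests demonstrates the pipeline's mechanics, not
performance on mechanistically heterogeneous panels.

### A structural limit on consensus recovery

With m collinear actives sharing one effect equation, each active's
population correlation with the indicator is ~1/√m (≈0.45 at m = 5), while
the sample |r| of the 45 inactive peaks at n = 12 groups has sd ≈ 0.30.  A
top-5 Pearson rule therefore captures ~3 of 5 actives per indicator, and
because every indicator shares the same group-mean draws, the union across
indicators barely improves on one: measured across seeds, union sensitivity
averages ≈0.45 and exceeds 0.8 for ~1 seed in 20.  This cap is intrinsic to
top-k screening of collinear actives, not a defect of any one engine —
VIP ≥ 1 alone, which is not top-k-limited, recovers ≈0.7–1.0 of the actives
on the same data.  Driving indicator noise to zero does not lift the cap
(the 1/√m dilution persists); with a single active and zero noise the
pipeline provably recovers it (sensitivity 1), which is what the noise-free
test asserts.

## Numerical choices

Ties in every ranking break toward the lexicographically lower peak id.
Even-count medians are the midpoint of the central order statistics.
Constant peaks are skipped in Pearson (r undefined) and zeroed in
standardization.  Zero-variance responses, single-class OPLS-DA, empty AHP
matrices and all-constant EWM panels raise validation errors.  Power
iteration and NIPALS tolerances are 1e−12/1e−10; orthogonality of predictive
vs orthogonal scores holds to <1e−8 and is asserted.  Seeds: every
stochastic component (generator, shuffled CV folds, permutation test) takes
an explicit seed and is bit-reproducible; the pipeline manifest records it.
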