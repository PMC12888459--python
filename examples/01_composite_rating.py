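"""Rate four formulations with the published AHP–entropy composite weights.

Loads the packaged positively-transformed pharmacodynamic panel (seven
indicators across formulations PW1–PW4) and the published seven-indicator
weight vector, then computes the weighted composite efficacy score per
formulation.
"""

from specscreen import WeightScheme, composite_score, load_fixture

panel = load_fixture("table6")
weights = WeightScheme(load_fixture("weights"))

print("indicator weights (%):")
for ind, w in weights.weights.items():
    print(f"  {ind:<22s} {100 * w:5.2f}")

scores = composite_score(panel, weights)
print("\ncomposite efficacy score per formulation (best first):")
for grp, s in scores.items():
    print(f"  {grp}  {s:6.2f}")

# A higher score means a better overall therapeutic profile across all
# seven indicators; the ordering PW4 > PW3 > PW2 > PW1 identifies the
# wine-processed / processed-fruit combination as the most effective.
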