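"""Classify the 260 unclassified MSH6 variants from their joint scores.

Applies the 0.56 pathogenicity cut-off (and the 0.65 impaired-function
boundary) to the packaged joint-score table and prints the resulting split.
About one third of the unclassified variants come out pathogenic.
"""

from codp import classify_impact, load_uv_scores

uv = load_uv_scores()
calls = [classify_impact(q) for q in uv["score"]]

n = len(calls)
n_path = sum(c.pathogenic for c in calls)
print(f"{n} unclassified variants")
print(f"  pathogenic (q > 0.56):      {n_path} ({100 * n_path / n:.1f}%)")
print(f"  non-pathogenic (q <= 0.56): {n - n_path} ({100 * (n - n_path) / n:.1f}%)")

examples = ["L370S", "G670V", "S9G"]
for name in examples:
    row = uv[uv["variant"] == name].iloc[0]
    call = classify_impact(row["score"])
    print(f"  {name}: q = {row['score']:.3f} -> {call.category.value}")
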