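"""Label variant carriers as LLS / ULS from clinical and molecular evidence.

Runs the rule engine over the packaged table of 34 curated MSH6 carriers
(IHC, MSI, functional assays, segregation, family history, allele
frequency) and prints the label counts plus one full rule-firing trace.
"""

from codp import classify_evidence_table, load_classified_variants

carriers = load_classified_variants()
result = classify_evidence_table(carriers)

counts = result["label"].value_counts()
print(f"{len(result)} carriers classified:")
print(f"  LLS (likely Lynch syndrome / pathogenic):   {counts.get('LLS', 0)}")
print(f"  ULS (unlikely Lynch syndrome / benign):     {counts.get('ULS', 0)}")

row = result[result["variant"] == "S1188N"].iloc[0]
print(f"\n{row['variant']} -> {row['label']} via {row['criteria_met']}")
for step in row["trace"].split(" | "):
    print(f"  {step}")
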