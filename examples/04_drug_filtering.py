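"""Filter a drug catalog against an expression signature.

Biomarkers with abnormal expression define a signature; the regulation
filter keeps drugs whose CMap-style connectivity score opposes each
biomarker's direction (|score| >= 0.5), the toxicity filter keeps drugs
with predicted LD50 >= 500 mg/kg, and a greedy set cover assembles the
smallest multi-molecule combination treating every biomarker.
"""

from gwgen import design_drugs, make_drug_catalog_fixture

signature = {"AKT1": "up", "BRCA1": "down", "FOXC1": "up",
             "MMP2": "up", "STAT3": "up"}
catalog = make_drug_catalog_fixture(sorted(signature), seed=0,
                                    directions=signature)
print(f"catalog: {catalog['drug'].nunique()} drugs x {catalog['target'].nunique()} targets")

proposal = design_drugs(catalog, signature, min_abs_score=0.5, min_ld50=500.0)
print(f"selected drugs: {proposal.drugs}")
print("coverage matrix (1 = drug treats biomarker):")
print(proposal.coverage.to_string())
if proposal.uncovered:
    print(f"uncovered biomarkers: {proposal.uncovered}")
# an upregulated biomarker needs a negative (signature-reversing) score;
# a downregulated one a positive score.  LD50 is kept as a safety margin.
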