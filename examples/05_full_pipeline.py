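"""One-call end-to-end run with a written report.

run_screen simulates every assay from one planted truth and analyses them;
write_report exports the main tables to markdown, write_dataset dumps the
raw CSVs plus a manifest for reanalysis.
"""

import os

import endosyncom as es

result = es.run_screen(seed=42)

print("Classes:", result.classification["label"].value_counts().to_dict())
print("SynCom sizes:", {k: len(v.members) for k, v in result.syncoms.items()})
root = result.pot_outcomes.query(
    "phenotype == 'root_length_cm' and design == 'TPB&TPF'"
).iloc[0]
print(
    f"TPB&TPF root length: {root['pct_vs_ck']:+.1f}% vs CK, "
    f"{root['pct_vs_abf']:+.1f}% vs ABF (letter {root['letter']})"
)

outdir = os.path.join("scratch", "example_run")
os.makedirs(outdir, exist_ok=True)
es.write_report(
    {
        "Growth classification": result.classification,
        "Phylum contingency": result.contingency.reset_index(),
        "PGPT ability counts": result.pgpt.reset_index(),
        "Pot outcomes": result.pot_outcomes,
    },
    os.path.join(outdir, "report.md"),
)
es.write_heatmap_matrix(
    result.matrices["bb_vshape"].wide, os.path.join(outdir, "bb_interaction_matrix.csv")
)
manifest = es.write_dataset(
    outdir, {"dose_response": result.dose}, truth=result.truth, parameters={"seed": 42}
)
print(f"\nReport, interaction matrix and raw data written under {outdir}/")
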