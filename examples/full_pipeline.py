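"""The whole funnel on a synthetic druggable genome.

Simulates 50 druggable genes (5 with a real expression->disease effect),
writes the input bundle to disk, runs every pipeline stage, and prints the
stage funnel plus the prioritized targets with their drug candidates —
the same audit trail the pipeline would produce on real summary statistics.
"""

import json
import tempfile
from pathlib import Path

from targetmr import synth
from targetmr.pipeline import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    bundle = synth.simulate_bundle(n_genes=50, n_causal=5, seed=42)
    paths = synth.write_bundle(bundle, Path(tmp) / "bundle", seed=42)
    config = RunConfig(
        eqtl_path=str(paths["eqtl"]), gwas_path=str(paths["gwas"]),
        genes_path=str(paths["genes"]), ld_dir=str(paths["ld_dir"]),
        blocklist_path=str(paths["blocklist"]),
        drug_table_path=str(paths["drugs"]),
        output_dir=str(Path(tmp) / "out"), seed=42)
    manifest = run_pipeline(config)

    print("stage funnel (counts at each gate):")
    print(json.dumps(manifest["counts"], indent=2, sort_keys=True))

    implanted = sorted(g for g, t in bundle.truths.items()
                       if t.scenario == "causal_shared")
    print(f"\nimplanted causal genes: {', '.join(implanted)}")
    print("prioritized targets (q < 0.05 AND PP4 > 0.75), with drug triage:")
    for line in (Path(tmp) / "out" / "prioritization.tsv").read_text().splitlines():
        if not line.startswith("#"):
            print("  " + line)
print("\nA perfect run recovers the implanted genes and nothing else; "
      "level_passed 3 marks approved, specific, safe drug candidates.")
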