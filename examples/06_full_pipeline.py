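"""The one-shot pipeline: stats -> predict -> evaluate -> peaks.

Writes a synthetic target (PDB + aligned FASTA) to a temporary
directory, drives the whole run from a single YAML configuration, and
prints the resulting peak table. Re-running the same configuration is
byte-identical.
"""

import tempfile
from pathlib import Path

import yaml

import contactbench as cb

tmp = Path(tempfile.mkdtemp())
prot = cb.generate(cb.GeneratorConfig(n_residues=60, n_sequences=100, seed=5))
cb.write_pdb(prot.coords, tmp / "t1.pdb")
cb.write_fasta(prot.aln, tmp / "t1.fasta")

config = {
    "seed": 1,
    "outdir": str(tmp / "run"),
    "rnd": {"n_reps": 50},
    "targets": [
        {"name": "t1", "msa": str(tmp / "t1.fasta"), "pdb": str(tmp / "t1.pdb"),
         "chain": "A", "offset": 0}
    ],
    "methods": {
        "ENT": {"kind": "range", "score": "ent", "center": "calibrate",
                "centers": [0.0, 0.25, 0.5, 0.75, 1.0], "half_width": 0.25},
        "KOL": {"kind": "range", "score": "kol", "center": "calibrate",
                "centers": [round(0.05 * i, 2) for i in range(1, 21)],
                "half_width": 0.10},
    },
}
cfg_path = tmp / "run.yaml"
cfg_path.write_text(yaml.safe_dump(config))

result = cb.run_all(cb.RunConfig.from_yaml(cfg_path))
print("outputs in", tmp / "run", "->",
      sorted(p.name for p in (tmp / "run").iterdir()))
print("\npeak table:")
print(result["peaks"].to_string(index=False))
print("\nThe primary peak is each method's characteristic contact distance")
print(f"on this target (generator truth: {prot.cfg.contact_radius:g} A).")
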