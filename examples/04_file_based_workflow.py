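"""File-based workflow: PDB + aligned FASTA in, TSV/JSON reports out.

Writes a synthetic complex to standard formats (PDB, aligned FASTA, ddG TSV)
and then runs the same analysis from files, exactly as the `consite` command
line would:

    consite simulate --seed 7 --out fixture/
    consite cluster --pdb fixture/complex.pdb --msa fixture/chainA.fasta \
        --chains-a A --chains-b B --out analysis/

For a real case, point --pdb at a crystal structure and --msa at an aligned
FASTA of homologues of the analyzed chain (first row = that chain's sequence).
"""

import json
import tempfile
from pathlib import Path

from consite import RunConfig, run_interface_analysis, write_alignment, write_structure
from consite.enrichment import write_ddg_table
from consite.synthetic import (
    FixtureSpec,
    make_alignment,
    make_complex,
    make_hotspot_annotations,
)

workdir = Path(tempfile.mkdtemp(prefix="consite_example_"))
spec = FixtureSpec(seed=7)
model, truth = make_complex(spec)
alignment = make_alignment(spec, truth, model.subset(["A"]))
annotations = make_hotspot_annotations(truth, inside_fraction=0.5, n_hot=4, seed=7)

write_structure(model, workdir / "complex.pdb")
write_alignment(alignment, workdir / "chainA.fasta")
write_ddg_table(annotations, model.residue_names(), workdir / "ddg.tsv")

config = RunConfig(
    pdb_path=str(workdir / "complex.pdb"),
    msa_path=str(workdir / "chainA.fasta"),
    ddg_path=str(workdir / "ddg.tsv"),
    chains_a=("A",), chains_b=("B",),
    flavor="complex", seed=7,
    out_dir=str(workdir / "analysis"),
)
report = run_interface_analysis(config)

payload = json.loads((workdir / "analysis" / "report.json").read_text())
print("wrote:", sorted(p.name for p in (workdir / "analysis").iterdir()))
print("rho =", payload["clustering"]["rho"], " p =", payload["random_test"]["p_empirical"])
print("config hash stamped in the report:", payload["config_hash"])
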