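"""One-command pipeline: simulate a screen, run every stage, inspect outputs.

Writes a synthetic dataset to disk in the package's interchange formats,
then runs the full profiling + conservatism + growth pipeline over those
files exactly as the command-line interface would, and prints the manifest
that makes the run reproducible.
"""

import json
import tempfile
from pathlib import Path

from exomedium import RunConfig, SimulationConfig, run_pipeline, write_simulation

with tempfile.TemporaryDirectory() as tmp:
    sim = Path(tmp) / "sim"
    paths = write_simulation(sim, SimulationConfig(seed=42))
    print("simulated inputs:", ", ".join(sorted(p.rsplit('/', 1)[-1] for p in paths.values())))

    out = Path(tmp) / "results"
    manifest = run_pipeline(
        RunConfig(
            peaks=paths["peaks"], samples=paths["samples"], tree=paths["tree"],
            groups=paths["taxa"], growth=paths["growth"], plate_map=paths["map"],
            n_perm=199, seed=42,
        ),
        out,
    )
    print("pipeline outputs: ", ", ".join(manifest["outputs"]))

    report = json.loads((out / "association.json").read_text())
    print()
    print(f"Mantel p = {report['p_value']:.4f}  "
          f"(rho = {report['rho']:.3f}, {report['n_perm']} permutations)")
    print(f"within-family similarity p = {report['group_test']['p_value']:.2e}")
    counts = (out / "depleted_counts.tsv").read_text().splitlines()
    print("most-depleting isolates:",
          ", ".join(sorted(counts[1:], key=lambda r: -int(r.split('\t')[1]))[:3]))
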