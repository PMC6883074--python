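"""Configuration-driven pipeline over two constructs.

Writes two synthetic constructs (sealed WT-like, leaky mutant-like) to
standard trajectory formats, builds a YAML run configuration, and runs
the flux analysis over replicates, producing per-replicate CSVs and a
JSON report with replicate means +/- SEM.
"""

import tempfile
from pathlib import Path

import yaml

from valvewatch import BarrierSystemParams, generate_barrier_system, run, validate_config
from valvewatch.synthetic import write_system

workdir = Path(tempfile.mkdtemp(prefix="valvewatch_demo_"))
constructs = {}
for label, prob in (("WT", 0.0), ("L554A L555A", 0.5)):
    replicates = []
    for seed in (1, 2):
        params = BarrierSystemParams(
            n_waters=120, n_frames=400, crossing_probability=prob, seed=seed
        )
        trajectory, _ = generate_barrier_system(params)
        paths = write_system(workdir / f"{label.replace(' ', '_')}_{seed}", trajectory)
        replicates.append(paths)
    constructs[label] = {
        "topology": str(replicates[0]["topology"]),
        "trajectories": [str(p["trajectory"]) for p in replicates],
    }

config_path = workdir / "config.yaml"
config_path.write_text(yaml.safe_dump({
    "constructs": constructs,
    "analyses": {"flux": {}},
    "equilibration_ns": 0.2,
    "output_dir": str(workdir / "out"),
}))

report = run(validate_config(config_path))
for label, analyses in report.summaries.items():
    flux = analyses["flux"]
    print(f"{label}: flux mean {flux['mean']:.1f} +/- {flux.get('sem', 0):.1f} "
          f"(replicates {flux['per_replicate']})")
print(f"\nartifacts in {workdir}/out; the report records package version,")
print("config hash and seed so a rerun is byte-identical.")
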