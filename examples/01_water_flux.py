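"""Count water crossings through the di-leucine valve.

Builds two synthetic solvent systems — one with a sealed hydrophobic
barrier (wild-type-like) and one with a permeable barrier emulating the
L554A L555A double mutant — and counts water exchange events between the
central and upper cavity flux boxes (2 x 2 x 2 nm each, split at the
valve plane, analysed every 10 ps).
"""

from valvewatch import (
    BarrierSystemParams,
    count_crossings,
    flux_summary,
    generate_barrier_system,
)

for label, prob in (("sealed (WT-like)", 0.0), ("leaky (L554A L555A-like)", 0.5)):
    records = []
    for seed in (1, 2, 3):
        params = BarrierSystemParams(
            n_waters=150, n_frames=1000, crossing_probability=prob, seed=seed
        )
        trajectory, ground_truth = generate_barrier_system(params)
        records.append(count_crossings(trajectory, stride_ps=10.0))
    summary = flux_summary(records)
    print(f"{label}: {summary.mean:.1f} +/- {summary.sem:.1f} crossings "
          f"per 10 ns (replicates: {summary.per_replicate})")

print()
print("A sealed valve passes no water at all; the leaky valve shows constant")
print("exchange - the contrast the crossing counter is built to quantify.")
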