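"""A configured sweep written to disk, as the command-line tool would run it.

Equivalent shell command:

    cerenkov-sim simulate --delta-beta 0.001 --delta-beta unlimited \
        --events 100 --seed 4 --out sweep_out
"""

from pathlib import Path

import cerenkovmc as c

cfg = c.RunConfig(
    n_events=100,
    delta_beta=[1e-3, None],
    seed=4,
    output_dir="sweep_out",
    optical_transport=True,
)
summaries = c.run_experiment(cfg)

for s in summaries:
    label = "unlimited" if s.delta_beta is None else f"{s.delta_beta:g}"
    print(f"delta_beta={label}: mean step {s.mean_step_length_um:.3f} um, "
          f"Cerenkov mean {s.cerenkov_fit_mean:.1f}, detected {s.n_detected}")

print("files written:", ", ".join(sorted(p.name for p in Path("sweep_out").iterdir())))
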