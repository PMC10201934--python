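"""Cerenkov photon transport and detection timing in the front geometry.

Traces every Cerenkov photon through the 3 x 3 x 20 mm wrapped BGO crystal
to the grease-coupled photodetector on the entrance face.  Forward-emitted
photons need at least one back-face reflection (> 20 mm of path); photons
emitted backward by a direction-scrambled electron reach the detector
directly within a few mm.
"""

import numpy as np

import cerenkovmc as c

bgo = c.make_bgo()
tables = c.build_loss_tables(bgo)
sampler = c.CerenkovSampler(bgo.dispersion)

for label, db, mode in (("unlimited", None, "mean-beta"), ("0.04%", 4e-4, "local")):
    s, raw = c.run_single(bgo, db, 300, seed=33, tables=tables, sampler=sampler,
                          optical_transport=True, yield_mode=mode)
    paths = np.array([d.path_length for d in raw.detected if d.kind == "cerenkov"])
    transits = np.array([d.transit_time for d in raw.detected if d.kind == "cerenkov"])
    print(f"delta_beta {label:>9}: detected {s.n_detected}/{s.n_emitted} Cerenkov photons")
    print(f"    path length: median {np.median(paths):6.1f} mm, "
          f"fraction beyond 20 mm {np.mean(paths > 20):.2f}")
    print(f"    transit time: median {np.median(transits):.3f} ns, "
          f"mean {s.mean_transit_ns:.3f} ns, "
          f"fraction below 0.15 ns {np.mean(transits < 0.15):.2f}")
print("-> fine stepping adds a prompt sub-0.1 ns population of backward "
      "photons that a coarse-step simulation never produces")
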