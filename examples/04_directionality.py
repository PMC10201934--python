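"""Loss of Cerenkov photon directionality with fine electron stepping.

Photons are emitted on a cone about the electron direction.  With long
steps the electron barely scatters before most photons are out, so photons
keep the forward direction of the incident gamma; with micrometre steps
the electron isotropises after a few tens of micrometres and later photons
point anywhere -- including backward, straight at the photodetector.
"""

import numpy as np

import cerenkovmc as c

bgo = c.make_bgo()
tables = c.build_loss_tables(bgo)
sampler = c.CerenkovSampler(bgo.dispersion)

for label, db, mode in (("unlimited", None, "mean-beta"), ("0.04%", 4e-4, "local")):
    s, _ = c.run_single(bgo, db, 300, seed=21, tables=tables, sampler=sampler,
                        optical_transport=False, yield_mode=mode)
    fr = s.backward_fractions
    early = np.mean([fr[o] for o in (1, 2, 3) if o in fr])
    late = np.mean([fr[o] for o in (9, 10, 11) if o in fr])
    print(f"delta_beta {label:>9}: backward fraction (within +/-5 deg of 180 deg) "
          f"photon 1-3: {early:.3f}   photon 9-11: {late:.3f}")
print("-> with fine steps the later-emitted photons drift backward; with "
      "range-sized steps every photon of the first eleven stays forward")
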