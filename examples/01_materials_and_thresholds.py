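"""Material optical properties and the Cerenkov emission threshold in BGO.

Builds the BGO radiator, prints its dispersion endpoints, the velocity and
kinetic-energy threshold for Cerenkov emission, and the Frank-Tamm photon
yield of a fresh 0.420 MeV photoelectric recoil electron.
"""

import cerenkovmc as c

bgo = c.make_bgo()

print(f"{bgo.name}: density {bgo.density} g/cm^3, mean excitation energy "
      f"{bgo.mean_excitation_ev:.0f} eV")
print("composition:", ", ".join(f"{e.symbol} {e.mass_fraction:.3f}" for e in bgo.elements))

d = bgo.dispersion
print(f"refractive index: {c.refractive_index(d, c.wavelength_nm_to_ev(320)):.2f} at 320 nm "
      f"-> {c.refractive_index(d, c.wavelength_nm_to_ev(800)):.2f} at 800 nm")

beta_t, ke_t = c.cherenkov_threshold(d)
print(f"Cerenkov threshold: beta > {beta_t:.4f}  (kinetic energy > {ke_t*1e3:.1f} keV)")

beta, gamma = c.kinematics(0.420)
y = c.yield_per_mm(beta, d)
print(f"a 0.420 MeV recoil electron (beta = {beta:.4f}) radiates {y:.1f} Cerenkov "
      f"photons per mm of path while at full speed")
print("-> the electron stops within ~0.3 mm, so each 511 keV interaction "
      "produces only a couple of tens of photons in total")
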