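"""Dosimetry of the solenoid-pair electromagnetic bioreactor.

Maps the vertical field component over the culture plane for the calibrated
coil pair, then derives the exposure figures: peak field, spatial
homogeneity, magnetic energy density and the induced electric field at the
edge of a 35 mm culture dish.
"""

from cardiokin.fieldmodel import (
    default_bioreactor,
    energy_density,
    homogeneity,
    induced_e_field,
    pair_field_map,
)

pair, waveform = default_bioreactor()
print(f"coils: R = {pair[0].radius * 100:.0f} cm, L = {pair[0].length * 100:.0f} cm, "
      f"{pair[0].n_turns} turns each, centers at z = +-{pair[1].z_center * 100:.0f} cm")
print(f"current pulse: 0 -> {waveform.i_peak * 1e3:.0f} mA in "
      f"{waveform.rise * 1e3:.2f} ms, repeated at {waveform.frequency:.0f} Hz")

fmap = pair_field_map(pair, waveform.i_peak, extent=0.04, n_samples=81)
b0 = fmap.center_bz
print(f"\ncenter field B_z: {b0:.3f} mT (transverse components "
      f"{(fmap.bt_x.max() / b0) * 100:.2f}% of B_z at most)")
print(f"homogeneity over the central 30% region: "
      f"{homogeneity(fmap) * 100:.2f}% max deviation")
print(f"magnetic energy density: {energy_density(b0 * 1e-3):.3f} J/m^3")

dbdt = b0 * 1e-3 / waveform.rise
print(f"dB/dt on the ramp: {dbdt:.2f} T/s")
print(f"induced E at r = 17.5 mm (dish edge): "
      f"{induced_e_field(0.0175, dbdt) * 1e3:.1f} mV/m")
# the ~2.8 mT center field and ~3.2 J/m^3 energy density characterize the
# exposure the beating syncytia receive in the EMF arms
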