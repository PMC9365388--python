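"""Estimate a bacterium's magnetic moment from its magnetosome census.

Electron microscopy gives the mean number of magnetosome crystals per cell
and their mean radius. The chain moment is the total magnetite volume times
the magnetite moment density; the uncertainty follows from standard error
propagation (the radius enters cubed, hence the factor of three).
"""

from trapswim import theory

stats = theory.MagnetosomeStats(N=23.8, dN=8.3, Rm=19.4, dRm=4.3, rhoM=4.8e-22)
M = theory.magnetic_moment(stats)
dM = theory.moment_uncertainty(M, stats)

print(f"census: N = {stats.N} +/- {stats.dN} crystals, "
      f"Rm = {stats.Rm} +/- {stats.dRm} nm")
print(f"moment:      M  = {M:.3e} A m^2  ({M * 1e12:.3e} A um^2)")
print(f"uncertainty: dM = {dM:.3e} A m^2  (dM/M = {dM / M:.2f})")

B, T = 500e-6, 305.0
alpha = theory.energy_ratio(M * 1e12, B, T)
print(f"at B = {B * 1e6:.0f} uT, T = {T:.0f} K: mB/kBT = {alpha:.1f} "
      f"-> U-turn radius at 40 um/s: "
      f"{theory.uturn_radius_alpha(alpha, 40.0):.1f} um")
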