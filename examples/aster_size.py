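"""Measure aster size with the twice-background threshold statistic.

The aster's outer radius is defined as the radius where the median
microtubule fluorescence, scanned outward from the disordered core, first
falls to twice the background level. The generator places that crossing
analytically so the measurement can be checked against ground truth.
"""

import astermodel as am

for target in (60.0, 85.0, 110.0):
    spec = am.MtProfileSpec(
        amplitude=2.0, background=0.1,
        outer_radius_target=target, depletion_r=target + 20.0,
    )
    prof = am.make_mt_profile(spec, bin_width=0.65, r_max=200.0)
    measured = am.aster_outer_radius(prof, prof.background, r_core=15.0)
    print(f"placed crossing at {target:6.1f} um -> measured {measured:7.2f} um")

print("\nThe statistic interpolates between radial bins, so recovery is")
print("accurate to a fraction of the 0.65 um bin width.")
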