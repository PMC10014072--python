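"""Predict the motor distribution in an aster from its microtubule profile.

Builds a synthetic microtubule profile with a core plateau, evaluates the
closed-form steady-state motor distribution for effective parameters
(Kd, λ0, C), splits it into bound and free fractions, and cross-checks the
closed form against a direct relaxation of the governing two-species
transport equations.
"""

import numpy as np

import astermodel as am
from astermodel.types import RadialProfile, RateParams

# microtubule concentration: plateau inside the 15 μm disordered core,
# exponential decay beyond, in arbitrary fluorescence units
spec = am.MtProfileSpec(family="exponential", amplitude=2.0, background=0.0,
                        decay_scale=20.0)
rho = am.make_mt_profile(spec, bin_width=0.5, r_max=100.0)

params = am.ModelParams(Kd=0.5, lambda0=20.0, C=1.0)
m_tot = am.steady_state_motor_profile(rho, params)
m_b, m_f = am.bound_free_split(rho, m_tot, params.Kd)

print("r [um]   rho_MT   m_tot   bound_frac")
for i in range(0, rho.r_centers.size, 40):
    print(f"{rho.r_centers[i]:6.1f} {rho.values[i]:8.3f} {m_tot.values[i]:7.3f}"
          f" {m_b.values[i] / m_tot.values[i]:10.3f}")

# independent check: relax the bound/free PDEs in the fast-binding regime
# (kon, koff much faster than transport) and compare total motor profiles
sig = rho.restrict(15.0, 100.0)
rates = RateParams(kon=2000.0, koff=1000.0, D=1.0, v=1.0 / 20.0)  # Kd=0.5, λ0=20
res = am.relax_two_species_pde(sig, rates, grid_n=200)
pde_tot = res.m_b.values + res.m_f.values
closed = am.steady_state_motor_profile(
    RadialProfile(res.m_b.r_centers,
                  np.interp(res.m_b.r_centers, sig.r_centers, sig.values)),
    params,
)
scale = pde_tot[-1] / closed.values[-1]
err = np.max(np.abs(pde_tot - scale * closed.values)) / pde_tot.max()
print(f"\nPDE relaxation vs closed form: sup-norm deviation {100 * err:.3f}%")
print("Motors pile up toward the center both by binding (isotherm factor)")
print("and by walking inward (exponential factor); the two routes agree.")
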