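"""Dimensionless groups for the study's flow conditions.

Builds the nanofluid (printed density 5.24 g/mL, water viscosity at 25 C)
and the 4 mm x 47 mm channel, then prints the numbers that set the
transport regime.
"""

import nanoflux as nf

for v in (0.0051, 0.0054):
    fc = nf.study_flow_conditions(v)
    print(f"mean velocity {v} m/s -> Re = {nf.reynolds_number(fc):.1f}, "
          f"entrance length = {nf.entrance_length(fc) * 1e3:.1f} mm")

fc = nf.study_flow_conditions(0.0051)
for form in nf.STUDY_FORMULATIONS:
    D = nf.stokes_einstein_diffusivity(form.hydrodynamic_diameter, fc.fluid)
    pe = nf.peclet_number(fc, D)
    print(f"{form.hydrodynamic_diameter * 1e9:5.0f} nm: D_B = {D:.3g} m^2/s, "
          f"Pe = {pe:.3g}")

# Re ~ 120-127 (laminar), entrance length > half the channel (entry flow
# matters), Pe ~ 6e6 (deposition is limited to a thin diffusive wall layer).
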