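"""Physical constants shared across the package (SI unless noted)."""

#: Universal gas constant (J mol⁻¹ K⁻¹).
R_GAS = 8.314462618

#: Body temperature (K) at which all gas-phase conversions are evaluated.
T_BODY = 310.15

#: One millimeter of mercury in pascal.
PA_PER_MMHG = 101325.0 / 760.0

#: Ideal-gas pressure-to-concentration ratio R·T at body temperature,
#: expressed in mmHg·m³·mol⁻¹: partial pressure (mmHg) = RT_MMHG · concentration.
RT_MMHG = R_GAS * T_BODY / PA_PER_MMHG

#: Standard atmosphere (Pa), used to convert volumetric O₂ demands to moles.
ATM_PA = 101325.0
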