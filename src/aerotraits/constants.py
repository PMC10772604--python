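"""Physical constants shared across the package."""

#: Boltzmann constant in eV/K (CODATA 2018).
K_B = 8.617333262e-5

#: Partial pressure of O2 in the surface atmosphere, atm.
P_ATM_O2 = 0.21

#: Partial pressure of O2 in dry air, atm (mole fraction 0.20946 at 1 atm);
#: used for solubility-based conversions from dissolved concentration.
P_O2_DRY_AIR = 0.20946

#: Default reference temperature for trait definitions, degrees Celsius.
T_REF_DEFAULT = 15.0

#: Celsius -> Kelvin offset.
CELSIUS_OFFSET = 273.15

#: Mean Earth radius, m (spherical geometry for grid-cell volumes).
EARTH_RADIUS_M = 6.371e6
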