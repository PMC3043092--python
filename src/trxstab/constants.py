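"""Physical constants and package-wide defaults.

Units follow the conventions of the protein-stability literature:
energies in kcal/mol, denaturant concentrations in M, temperatures in
degrees Celsius at the interface and Kelvin internally, lengths in
angstroms.
"""

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.987e-3

#: Celsius -> Kelvin offset.
CELSIUS_OFFSET = 273.15

#: Avogadro's number, mol^-1.
AVOGADRO = 6.02214076e23

#: Default temperature for chemical-denaturation fits (25 degC), K.
DEFAULT_TEMPERATURE_K = 298.15

#: Default partial specific volume for small globular proteins, cm^3/g.
DEFAULT_VBAR = 0.73

#: Standard fixed heat-capacity change for thermal fits, kcal mol^-1 K^-1.
DEFAULT_DCP = 1.2

#: Emission acquisition window (inclusive) and step used by the generators, nm.
WAVELENGTH_MIN = 300.0
WAVELENGTH_MAX = 400.0
WAVELENGTH_STEP = 1.0
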