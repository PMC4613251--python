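# Polyproline-II-oriented amide pi-pi* dispersive parameters.
#
# Package defaults: relative to the general-purpose OL set the oscillator is
# shifted to the red, matching the tendency of polyproline-II-tuned
# parameters to red-shift predicted spectra.
name = "J"
placement = "o"
bandwidth = 6000.0        # cm^-1, Lorentzian half-peak bandwidth

[dispersive]
nu0 = 51280.0             # cm^-1  (195.0 nm)
D = 2.4e9                 # A^3 cm^-2
theta = -15.0             # degrees from N->C' toward the carbonyl-O side
static_components = [0.70, 0.50, 0.30]   # A^3, residual amide tensor (e1,e2,e3)
static_phi = 0.0          # degrees

[isotropic]
C_aliphatic = 0.878       # A^3
O_alcohol = 0.465         # A^3
H_aliphatic = 0.135       # A^3
H_alcohol = 0.135         # A^3
H_amide = 0.161           # A^3
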