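# General-purpose amide pi-pi* dispersive parameters ("original"-style set)
# with NaD-line isotropic atom polarizabilities.
#
# These are the package defaults, calibrated so that an isolated oscillator
# absorbs near 190 nm with a zero-frequency polarizability contribution of
# ~0.9 A^3, and so that ideal alpha-helices reproduce the canonical far-UV
# exciton couplet (positive band near 190 nm, negative near 205-210 nm).
name = "OL"
placement = "o"
bandwidth = 6000.0        # cm^-1, Lorentzian half-peak bandwidth

[dispersive]
nu0 = 52630.0             # cm^-1  (190.0 nm)
D = 2.4e9                 # A^3 cm^-2; D/nu0^2 ~ 0.87 A^3
theta = -15.0             # degrees from N->C' toward the carbonyl-O side
static_components = [0.70, 0.50, 0.30]   # A^3, residual amide tensor (e1,e2,e3)
static_phi = 0.0          # degrees, in-plane rotation of static axes

[isotropic]
C_aliphatic = 0.878       # A^3
O_alcohol = 0.465         # A^3
H_aliphatic = 0.135       # A^3
H_alcohol = 0.135         # A^3
H_amide = 0.161           # A^3
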