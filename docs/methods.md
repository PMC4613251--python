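# Methods

## Model

The package implements the dipole interaction (coupled-oscillator) model of
optical activity for the amide π–π* transition. A protein is a set of N
polarizable points interacting through their induced dipole fields:

* one **dispersive point per peptide bond** — the amide N–C′–O group reduced
  to a single anisotropic point. It carries a Lorentzian oscillator of
  strength constant D_is (Å³·cm⁻²), wavenumber ν̄_is (cm⁻¹), and bandwidth Γ,
  polarized along an in-plane direction **u**, plus an optional
  frequency-independent residual tensor;
* one **isotropic point per parameterized nonchromophoric atom** — aliphatic
  C, alcohol O, and H species — with a scalar NaD-line polarizability;
* everything else (sulfur, metals, terminal carboxylate, free amine
  nitrogen, ligands, waters) is ignored and logged.

Only aliphatic residues (ALA, VAL, PRO, GLY, LEU, ILE) are treated in full;
all others are truncated at C-β and renamed ALA, which leaves the backbone
and all amide chromophores untouched. Proline's tertiary amide receives the
same chromophore parameters as a secondary amide; the run log counts
prolines so the approximation is visible.

### Local amide frame and chromophore placement

e1 = unit(N→C′); e3 = unit normal of the N–C′–O plane; e2 = e3 × e1 points
toward the carbonyl oxygen. The chromophore sits at the N–C′ midpoint
(placement `o`), or shifted 0.1 Å along the bond toward C′ (`x`), or 0.1 Å
in-plane toward the carbonyl O (`y`). The oscillator direction is
u = cos θ·e1 + sin θ·e2. Euler angles between successive amide frames are
reported in the z-y-z convention (with ψ = 0 at the gimbal singularity);
internally only rotation matrices are used, so the convention affects
reporting only.

### Eigenproblem and dimensional scaling

The zero-frequency interaction matrix uses one scalar coordinate per
dispersive oscillator (diagonal ν̄₀²/D, couplings u·T·u) and three Cartesian
coordinates per nondispersive unit (diagonal blocks α⁻¹, couplings T). A
unit never interacts with itself, so a chromophore's oscillator does not
couple to its own co-located residual tensor. The nondispersive block is
eliminated by a Schur complement computed through a Cholesky (or, if not
positive definite, LU) factorization — never an explicit inverse — with a
hard error if its condition number exceeds 1e12.

Because the raw matrix mixes units (cm⁻²·Å⁻³ diagonal vs Å⁻³ couplings),
the eigenproblem is posed on the symmetrically scaled matrix
G = S^{1/2}·(Schur complement)·S^{1/2} with S = diag(D_is). G carries cm⁻²
exactly: an isolated oscillator gives ν̄₀², two identical parallel
oscillators at separation R perpendicular to u split as ν̄₀² ± D/R³ (a
closed-form test), and for uniform D the scaling is a similarity transform
of the unscaled reduction. Mode amplitudes correspondingly acquire √D_is
weights in the moment sums,

    μ^(k) = Σ √D_is t_is u_is,   m^(k) = Σ √D_is t_is (r_i − o) × u_is,

which reduce to the unweighted sums for uniform D; the literal unweighted
convention is available (`--amplitudes as-printed`). Both conventions
satisfy the sum rules Σ_k D_k = Σ_is D_is (with D_is → 1 when unweighted)
and Σ_k R_k = 0, which the tests assert to 1e-8. Rotational strengths are
origin-independent (asserted); the magnetic-moment origin defaults to the
chromophore centroid.

Non-positive eigenvalues ("long-wavelength modes", the signature of
unrelaxed or colliding geometry) are retained, flagged, reported in the
mode table, and excluded from the spectral sums with a warning — never
silently dropped and never fatal.

### Spectra and units

Per-residue molar spectra follow the Lorentzian mode sums with prefactors
8π²ν̄²N_AΓ/6909p (absorption) and 32π³ν̄³N_AΓ/6909p (CD). The constant
6909 = 3 × 2303 already contains the orientational average (1/3) and the
decadic/molar conversion (1000·ln10), so the implementation's only unit
conversion is Å → cm on the strengths: D_k × 1e-24 and R_k × 1e-32. This
calibration is not taken on faith: the package also solves the full complex
system **A**(ν̄)**μ** = **E** directly at every grid point and derives the
extinction from −Im Σ_ij B_ij (u_i·u_j) over dispersive pairs; the two
routes agree to machine precision on mixed random systems (the acceptance
report's `mode_sum_vs_full_solve_max_rel_error`). The moment sums run over
dispersive oscillators only; back-induced moments on the nondispersive
points are not added to the observables, and the brute-force solver is the
tool for quantifying that approximation if needed.

Grids: 175–250 nm step 1 nm (survey route), 176–250 nm step 2 nm (rebuild
route); ν̄ = 10⁷/λ.

## Parameters

Each parameter family is one editable TOML file (units in comments):

| field | meaning | unit | OL default |
|---|---|---|---|
| `nu0` | oscillator wavenumber | cm⁻¹ | 52 630 (190 nm) |
| `D` | dipole-strength constant | Å³·cm⁻² | 2.4e9 (α₀ ≈ 0.87 Å³) |
| `theta` | oscillator angle from N→C′ toward O | deg | −15 |
| `static_components` | residual amide tensor principal values | Å³ | 0.70/0.50/0.30 |
| `bandwidth` | Lorentzian half-peak width Γ | cm⁻¹ | 6000 |
| `placement` | chromophore position convention | – | `o` |
| isotropic α | C 0.878, O 0.465, H 0.135–0.161 | Å³ | |

The three bundled families are package defaults, not literature
transcriptions: OL is the general-purpose set; H is blue-shifted
(ν̄₀ = 53 480 cm⁻¹, 187 nm) as helix-tuned sets tend to be; J is red-shifted
(ν̄₀ = 51 280 cm⁻¹, 195 nm) in the manner of polyproline-II-tuned sets. The
magnitudes were fixed once by physical reasoning: D/ν̄₀² near the known
zero-frequency amide polarizability, isotropic values from standard
NaD-line atom polarizabilities, and θ chosen so that an ideal α-helix built
by the package reproduces the canonical far-UV couplet (positive band near
190 nm of order +10 M⁻¹cm⁻¹ per residue, negative band near 208 nm, one
zero-crossing) — the qualitative morphology every helical protein
measurement shows. The test suite deliberately uses synthetic parameter
sets so that correctness never depends on these defaults. Bandwidth is the
single field a config may omit (default 6000 cm⁻¹, the width that tracks
experimental band shapes best); every other physics field must be explicit.

## Chain builder and rebuild route

Chains are grown by the natural-extension reference frame construction from
ideal internal coordinates (N–Cα 1.458, Cα–C′ 1.525, C′–N 1.329, C′=O
1.231, Cα–Cβ 1.521 Å; standard backbone angles), seeded with the first N at
the origin, Cα on +x, C′ in the xy-plane. Torsions round-trip exactly
(tested to 1e-6 degrees); C-β is placed with L-chirality (improper
N–C′–Cα–Cβ ≈ −120°); amide H, Hα and alanine methyl hydrogens are added at
ideal positions on request. An ideal α-helix (φ = −57°, ψ = −47°) shows a
rise of 1.56 Å per residue by an independent helix-axis fit (second
differences of the Cα trace), against the textbook 1.5 Å.

The rebuild route mutates untreated residues to alanine, measures torsions
from the input structure, rebuilds each user-designated fragment as its own
chain with hydrogens (ω retained by default, `idealize_omega` available),
and drops fragments that collide (non-bonded heavy atoms < 2 Å). If
dropped plus planned-ignored residues exceed 50% of the protein, the route
fails with a dedicated exit code. Fragment identification is user input;
no secondary-structure detection is performed.

## Comparison statistics

RMSD = sqrt(Σ(expΔε − calcΔε)²/n_λ) over a wavelength window (default
180–210 nm, the π–π* region), with the experimental spectrum linearly
interpolated onto the calculated grid (never extrapolated). Across a panel
of proteins, the Spearman rank correlation of calculated vs experimental Δε
at a fixed wavelength uses averaged ranks for ties.

## Numerical choices

* Minimum separation between distinct polarizable points: 0.5 Å (hard
  error naming the pair), warning below 1.5 Å. A chromophore and its own
  co-located static tensor are one unit and exempt.
* Altloc resolution: highest occupancy, ties by alphabetical label.
* Peptide bonds require consecutive residue numbering and C′–N < 2.0 Å;
  otherwise the chain is treated as broken fragments (each contributing
  p_frag − 1 amides) and no bond is ever created across chains.
* CH₃ groups are detected geometrically (a carbon with exactly three H
  within 1.2 Å and one heavy atom within 1.8 Å); hydrogen species are
  assigned by the nearest heavy atom, so naming dialects (HB1 vs 1HB) are
  irrelevant.
* Eigenvector signs are fixed (largest-magnitude component positive), so
  repeated runs give byte-identical outputs.
* Dense symmetric eigensolver throughout; no sparsity. Protein-scale
  problems (hundreds of oscillators, a few thousand nondispersive
  coordinates) are well within dense range.

## What the synthetic fixtures do and do not show

Tests and the acceptance report run on built ideal chains and random
well-separated oscillator systems. These exercise every algebraic property
of the method — sum rules, enantiomer antisymmetry, origin and rigid-motion
invariance, the Schur reduction, the equivalence of the normal-mode and
brute-force routes, and the qualitative helix couplet. They do not
establish quantitative agreement with measured protein spectra, which
additionally requires energy-minimized experimental structures and
empirically fitted amide parameters; with the bundled defaults the package
produces physically scaled spectra (helical Δε of order ±10 M⁻¹cm⁻¹ per
residue) but per-protein band positions and intensities will track the
parameter set used. Real measurements also contain the n–π* band near
220 nm, which this model deliberately omits.

## Known limitations

* Only the amide π–π* transition; no n–π* oscillator, no aromatic side-chain
  chromophores, no charge-transfer transitions, so spectra above ~215 nm are
  systematically incomplete.
* No energy minimization: structures must be pre-relaxed (the model is
  sensitive to the compressed bond lengths typical of crystal structures),
  or rebuilt through the fragment route.
* No ligands or metals; no mmCIF input; no solvent or retardation effects.
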