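# dipolecd

Far-UV circular dichroism (CD) of peptides and proteins from the classical
dipole interaction model.

## The problem and who this is for

The far-UV CD spectrum (roughly 175–250 nm) of a protein is dominated by the
π–π* transition of its backbone amides and is the workhorse observable for
secondary-structure analysis. `dipolecd` predicts that spectrum from a
three-dimensional structure using classical electromagnetic theory alone —
no wavefunctions, only empirically parameterized polarizabilities. It is
aimed at structural biologists and spectroscopists who want to compare a
model structure against a measured CD spectrum (e.g. a processed
synchrotron-CD databank entry), and at method developers who need a clean,
tested reference implementation of the coupled-dipole normal-mode formalism.

## The model

Each peptide bond's amide group (N, C′, O) is reduced to a single point with
anisotropic polarizability near the midpoint of the N–C′ bond, carrying one
dispersive oscillator with Lorentzian polarizability

    α_is(ν̄) = D_is u_is u_is / (ν̄_is² − ν̄² + iΓν̄),

polarized along the in-plane unit vector **u**_is. Aliphatic carbons,
alcohol oxygens, and (optionally) hydrogens become points with isotropic,
frequency-independent polarizability; all other atoms are ignored. The
induced moments satisfy **μ** = **A**⁻¹**E**, where the interaction matrix
**A** couples every pair of points through the dipole field tensor
T_αβ = (δ_αβ r² − 3 r_α r_β)/r⁵.

At ν̄ = 0 the matrix is real and symmetric. Partitioning it into a
dispersive (chromophoric) block and a nondispersive block and eliminating
the latter by a Schur complement, A°₁₁ − A₁₂ (A°₂₂)⁻¹ A₂₁, leaves an
eigenproblem over the q = p − 1 amide oscillators only (p = residues). Its
eigenvalues are squared normal-mode wavenumbers ν̄_k²; from the eigenvectors
**t**^(k) the electric and magnetic mode moments give dipole strengths
D_k = **μ**^(k)·**μ**^(k) and rotational strengths R_k = **μ**^(k)·**m**^(k),
and the per-residue spectra are Lorentzian sums over modes:

    ε(ν̄)  =  8π² ν̄² N_A Γ / (6909 p) · Σ_k D_k / ((ν̄_k² − ν̄²)² + Γ²ν̄²)
    Δε(ν̄) = 32π³ ν̄³ N_A Γ / (6909 p) · Σ_k R_k / ((ν̄_k² − ν̄²)² + Γ²ν̄²)

Two exact sum rules — Σ_k D_k = Σ_is D_is and Σ_k R_k = 0 — and a
brute-force complex solve of the full matrix on the wavelength grid serve as
internal oracles for every spectrum the package produces.

Two routes mirror common practice. The survey route (`calc`) takes an
energy-minimized structure as-is, mutates non-aliphatic residues to alanine
beyond C-β, and computes on a 175–250 nm / 1 nm grid. The rebuild route
(`capps`) re-constructs user-designated secondary-structure fragments with
ideal bond lengths and angles from the structure's own torsions before the
same calculation (176–250 nm / 2 nm); if collisions force more than 50% of
the residues to be dropped, the rebuild is declared a failure.

## Worked example

Build an 18-residue ideal α-helix (φ = −57°, ψ = −47°) and compute its CD
with the default general-purpose (OL) parameter set:

```
$ dipolecd build --n-res 18 --out helix18.pdb
wrote 18-residue chain to helix18.pdb
$ dipolecd calc helix18.pdb --params OL --out helix_run
INFO dipolecd: classified 18 residues: 17 dispersive oscillators, 36 isotropic points, 3 ignored atoms
INFO dipolecd: interaction matrix: q_d=17 dispersive, n_nd=159 nondispersive coordinates
wrote spectrum and reports to helix_run
```

The 18 residues give 17 amide chromophores; the 36 isotropic points are the
Cα and Cβ carbons (hydrogens are excluded by default, and the terminal
amine/carboxyl atoms are ignored). `helix_run/spectrum.csv` holds the
per-residue spectra; its extrema are

```
wavelength_nm,epsilon,delta_epsilon
194,2074.8,+8.73      <- positive π-π* couplet lobe
208,1776.3,-6.90      <- negative lobe
```

the canonical α-helical exciton couplet: a positive band near 190 nm, a
negative band near 205–210 nm, and a single zero-crossing between them.
`helix_run/modes.tsv` lists every normal mode's wavelength, dipole strength,
and rotational strength; `run.json` records the unit accounting. To compare
against a measurement,

```
$ dipolecd compare helix_run/spectrum.csv experiment.txt --window 180 210
RMSD = ... M^-1 cm^-1 over 180-210 nm (31 points)
```

where `experiment.txt` is two-column text (wavelength nm, Δε in M⁻¹cm⁻¹).

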