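"""Dipole interaction matrix, partially dispersive reduction, normal modes.

The coupled system of induced dipoles mu = B E (B the inverse interaction
matrix) is posed in a mixed basis: one scalar coordinate per dispersive
amide oscillator (the moment component along its polarization axis u) and
three Cartesian coordinates per nondispersive point.  At zero frequency the
matrix is real and symmetric; partitioning it into the dispersive block,
the nondispersive block, and their couplings,

    A0 = [[A11_0, A12], [A21, A22_0]],

the far-UV normal modes are those of the Schur complement
A11_0 - A12 A22_0^{-1} A21.

Units are mixed in the raw matrix (the dispersive diagonal is nu0^2/D in
cm^-2 A^-3 while couplings are A^-3), so the eigenproblem is posed on the
symmetrically scaled matrix

    G = S^{1/2} (A11_0 - A12 A22_0^{-1} A21) S^{1/2},   S = diag(D_is),

whose eigenvalues carry cm^-2 exactly: for an isolated oscillator G reduces
to nu0^2, and for uniform D the scaling is a similarity transform of the
unscaled reduction.  Eigenvalues are the squared normal-mode wavenumbers
nu_k^2; non-positive eigenvalues (long-wavelength modes, a symptom of
unrelaxed geometry) are retained and flagged, never silently dropped.

:func:`full_solve` is the brute-force oracle: it inverts the complete
complex frequency-dependent matrix on a wavenumber grid with no block
reduction and no eigendecomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .chromophore import PolarizableUnitSet
from .errors import ContactError, NumericalError, SingularBlockError

MIN_SEPARATION = 0.5   # A; closer pairs are a hard error
WARN_SEPARATION = 1.5  # A; closer pairs draw a warning

_CONDITION_LIMIT = 1e12


def dipole_field_tensor(
    ri: np.ndarray, rj: np.ndarray, min_separation: float = MIN_SEPARATION
) -> np.ndarray:
    """Point-dipole field tensor T_ij between positions ri and rj (A^-3).

    T_ab = (delta_ab r^2 - 3 r_a r_b) / r^5 with r = rj - ri.  Symmetric in
    its arguments and traceless.
    """
    r = np.asarray(rj, float) - np.asarray(ri, float)
    d = np.linalg.norm(r)
    if d < min_separation:
        raise ContactError(
            f"polarizable points separated by {d:.3f} A "
            f"(minimum {min_separation} A)"
        )
    return (np.eye(3) * d**2 - 3.0 * np.outer(r, r)) / d**5


@dataclass
class InteractionBlocks:
    """Zero-frequency interaction matrix partitioned dispersive/nondispersive.

    Nondispersive coordinates run three per nondispersive unit: the
    isotropic atoms, followed (when included) by one unit per chromophore
    carrying its residual static tensor, co-located with the oscillator.
    """

    A11_0: np.ndarray           # (q, q), diagonal nu0^2/D
    A12: np.ndarray             # (q, n_nd)
    A22_0: np.ndarray           # (n_nd, n_nd)
    nu0: np.ndarray             # (q,) oscillator wavenumbers, cm^-1
    D: np.ndarray               # (q,) dipole-strength constants, A^3 cm^-2

    @property
    def q_d(self) -> int:
        return self.A11_0.shape[0]

    @property
    def n_nd(self) -> int:
        return self.A22_0.shape[0]

    @property
    def A21(self) -> np.ndarray:
        return self.A12.T

    def full_matrix(self) -> np.ndarray:
        return np.block([[self.A11_0, self.A12], [self.A12.T, self.A22_0]])


def _check_separations(positions: np.ndarray, min_separation: float) -> None:
    n = len(positions)
    if n < 2:
        return
    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    iu = np.triu_indices(n, k=1)
    close = dist[iu] < min_separation
    if np.any(close):
        pairs = [
            (int(iu[0][k]), int(iu[1][k]), float(dist[iu[0][k], iu[1][k]]))
            for k in np.nonzero(close)[0][:10]
        ]
        detail = ", ".join(f"units {i}-{j} at {d:.3f} A" for i, j, d in pairs)
        raise ContactError(f"atomic collisions between polarizable points: {detail}")
    warn = (dist[iu] < WARN_SEPARATION) & ~close
    if np.any(warn):
        warnings.warn(
            f"{int(np.sum(warn))} polarizable point pair(s) closer than "
            f"{WARN_SEPARATION} A", stacklevel=3,
        )


def assemble(
    units: PolarizableUnitSet,
    include_chromophore_static: bool = True,
    min_separation: float = MIN_SEPARATION,
) -> InteractionBlocks:
    """Assemble the zero-frequency interaction matrix in block form.

    Diagonal entries are inverse polarizabilities (nu0^2/D for dispersive
    oscillators; the inverse tensor for nondispersive units); off-diagonal
    entries couple units through the dipole field tensor, projected on the
    oscillator axes for the dispersive coordinates.  A unit never interacts
    with itself, so a chromophore's oscillator does not couple to its own
    co-located static tensor.
    """
    q = units.q
    chrom = units.chromophores
    nd_positions = [a.position for a in units.isotropics]
    nd_tensors = [np.eye(3) / a.alpha for a in units.isotropics]
    nd_owner = [-1] * len(units.isotropics)  # chromophore index owning the unit
    if include_chromophore_static:
        for ci, c in enumerate(chrom):
            if np.allclose(c.alpha_static, 0.0):
                continue
            try:
                inv = np.linalg.inv(c.alpha_static)
            except np.linalg.LinAlgError:
                raise SingularBlockError(
                    f"static tensor of chromophore {ci} is singular"
                )
            nd_positions.append(c.position)
            nd_tensors.append(inv)
            nd_owner.append(ci)

    n_units = len(nd_positions)
    n_nd = 3 * n_units

    # separation check across all distinct units (co-located owner pairs exempt)
    pos_list = [c.position for c in chrom] + nd_positions
    owner_of = list(range(q)) + [o if o >= 0 else None for o in nd_owner]
    all_pos = np.array(pos_list).reshape(-1, 3)
    # exempt chromophore/own-static pairs by checking in two passes:
    # chromophores+isotropics strictly, then statics against non-owners.
    n_strict = q + len(units.isotropics)
    _check_separations(all_pos[:n_strict], min_separation)
    for k in range(n_strict, len(pos_list)):
        own = owner_of[k]
        for m in range(n_strict):
            if m == own:
                continue
            d = float(np.linalg.norm(all_pos[k] - all_pos[m]))
            if d < min_separation:
                raise ContactError(
                    f"chromophore static unit {own} collides with unit {m} "
                    f"at {d:.3f} A"
                )

    nu0 = np.array([c.params.nu0 for c in chrom])
    D = np.array([c.params.D for c in chrom])

    A11 = np.zeros((q, q))
    np.fill_diagonal(A11, nu0**2 / D)
    for i in range(q):
        for j in range(i + 1, q):
            T = dipole_field_tensor(chrom[i].position, chrom[j].position,
                                    min_separation)
            A11[i, j] = A11[j, i] = chrom[i].u @ T @ chrom[j].u

    A12 = np.zeros((q, n_nd))
    A22 = np.zeros((n_nd, n_nd))
    for a in range(n_units):
        A22[3 * a: 3 * a + 3, 3 * a: 3 * a + 3] = nd_tensors[a]
        for b in range(a + 1, n_units):
            T = dipole_field_tensor(nd_positions[a], nd_positions[b],
                                    min_separation)
            A22[3 * a: 3 * a + 3, 3 * b: 3 * b + 3] = T
            A22[3 * b: 3 * b + 3, 3 * a: 3 * a + 3] = T
    for i in range(q):
        for a in range(n_units):
            if nd_owner[a] == i:
                continue  # same unit: no self-interaction
            T = dipole_field_tensor(chrom[i].position, nd_positions[a],
                                    min_separation)
            A12[i, 3 * a: 3 * a + 3] = chrom[i].u @ T

    return InteractionBlocks(A11_0=A11, A12=A12, A22_0=A22, nu0=nu0, D=D)


def reduce_dispersive(blocks: InteractionBlocks) -> np.ndarray:
    """Schur complement A11_0 - A12 A22_0^{-1} A21 via a factorization.

    Returns A11_0 unchanged when there are no nondispersive units.  Raises
    :class:`SingularBlockError` when the nondispersive block is singular or
    its condition number exceeds 1e12.
    """
    if blocks.n_nd == 0:
        return blocks.A11_0.copy()
    A22 = blocks.A22_0
    if not np.all(np.isfinite(A22)):
        raise NumericalError("non-finite entries in the nondispersive block")
    cond = np.linalg.cond(A22)
    if not np.isfinite(cond) or cond > _CONDITION_LIMIT:
        # name the worst pivot for diagnosis
        diag = np.abs(np.diag(A22))
        worst = int(np.argmin(diag))
        raise SingularBlockError(
            f"nondispersive block ill-conditioned (cond={cond:.3g}); "
            f"smallest diagonal at coordinate {worst}"
        )
    try:
        cho = scipy.linalg.cho_factor(A22, check_finite=False)
        X = scipy.linalg.cho_solve(cho, blocks.A21, check_finite=False)
    except scipy.linalg.LinAlgError:
        lu = scipy.linalg.lu_factor(A22, check_finite=False)
        X = scipy.linalg.lu_solve(lu, blocks.A21, check_finite=False)
    R = blocks.A11_0 - blocks.A12 @ X
    return 0.5 * (R + R.T)


@dataclass
class NormalModeSet:
    """Normal modes of the reduced dispersive system.

    ``nu_k_sq`` are eigenvalues of the scaled reduction (cm^-2), ascending;
    column k of ``t`` is the orthonormal amplitude vector of mode k (sign
    fixed so its largest-magnitude component is positive).  ``flagged``
    marks non-positive eigenvalues (long-wavelength modes).
    """

    nu_k_sq: np.ndarray
    t: np.ndarray
    effective_matrix: np.ndarray
    D: np.ndarray
    flagged: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.flagged is None:
            self.flagged = self.nu_k_sq <= 0.0

    @property
    def n_modes(self) -> int:
        return len(self.nu_k_sq)

    def wavenumbers(self) -> np.ndarray:
        """nu_k in cm^-1; NaN for flagged (non-positive) modes."""
        out = np.full_like(self.nu_k_sq, np.nan)
        ok = ~self.flagged
        out[ok] = np.sqrt(self.nu_k_sq[ok])
        return out


def solve_modes(reduced: np.ndarray, D: np.ndarray) -> NormalModeSet:
    """Eigen-decompose the dimensionally scaled reduced matrix.

    ``reduced`` is the Schur complement (raw units); ``D`` the dispersive
    dipole-strength constants.  G = S^{1/2} reduced S^{1/2} with
    S = diag(D) is symmetric with eigenvalues in cm^-2.
    """
    reduced = np.asarray(reduced, float)
    D = np.asarray(D, float)
    if not np.all(np.isfinite(reduced)):
        raise NumericalError("non-finite entries in the reduced matrix")
    sqrtD = np.sqrt(D)
    G = reduced * np.outer(sqrtD, sqrtD)
    G = 0.5 * (G + G.T)
    w, v = np.linalg.eigh(G)
    order = np.argsort(w)
    w = w[order]
    v = v[:, order]
    # deterministic eigenvector sign: largest-magnitude component positive
    for k in range(v.shape[1]):
        idx = int(np.argmax(np.abs(v[:, k])))
        if v[idx, k] < 0:
            v[:, k] = -v[:, k]
    flagged = w <= 0.0
    if np.any(flagged):
        warnings.warn(
            f"{int(np.sum(flagged))} non-positive eigenvalue(s): "
            "long-wavelength modes suggest the geometry needs relaxation",
            stacklevel=2,
        )
    return NormalModeSet(nu_k_sq=w, t=v, effective_matrix=G, D=D,
                         flagged=flagged)


@dataclass
class FullSolveResult:
    """Direct complex solve of the coupled-dipole equations on a grid.

    For each wavenumber on the grid the complete interaction matrix
    (dispersive Lorentzian diagonal, equation-of-motion couplings) is
    inverted; ``mu`` holds induced moments for unit external fields and
    ``B`` the full inverse matrices.  ``trace_dispersive`` is the
    orientation-summed contraction sum_ij B_ij (u_i . u_j) over dispersive
    pairs -- the complex polarizability whose imaginary part carries
    absorption.
    """

    grid: np.ndarray                 # wavenumbers, cm^-1
    B: np.ndarray                    # (n_grid, N, N) complex
    mu: np.ndarray                   # (n_grid, N) complex, for E = 1 on each coord
    trace_dispersive: np.ndarray     # (n_grid,) complex, A^3
    q: int


def full_solve(
    units: PolarizableUnitSet,
    grid: np.ndarray,
    gamma: float,
    include_chromophore_static: bool = True,
) -> FullSolveResult:
    """Brute-force frequency-domain solve (the oracle path).

    Builds the full complex matrix A(nu) -- identical to the zero-frequency
    assembly except that each dispersive diagonal entry is
    (nu0^2 - nu^2 + i Gamma nu)/D -- and inverts it at every grid point.
    """
    grid = np.asarray(grid, float)
    if np.any(~np.isfinite(grid)) or np.any(grid <= 0):
        raise NumericalError("wavenumber grid must be finite and positive")
    blocks = assemble(units, include_chromophore_static=include_chromophore_static)
    q, n = blocks.q_d, blocks.n_nd
    A0 = blocks.full_matrix().astype(complex)
    N = q + n
    uu = np.zeros((q, q))
    for i in range(q):
        for j in range(q):
            uu[i, j] = units.chromophores[i].u @ units.chromophores[j].u

    B = np.empty((len(grid), N, N), dtype=complex)
    mu = np.empty((len(grid), N), dtype=complex)
    tr = np.empty(len(grid), dtype=complex)
    E = np.ones(N)
    for g, nu in enumerate(grid):
        A = A0.copy()
        A[np.arange(q), np.arange(q)] = (
            blocks.nu0**2 - nu**2 + 1j * gamma * nu
        ) / blocks.D
        try:
            Binv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            raise NumericalError(f"interaction matrix singular at {nu} cm^-1")
        B[g] = Binv
        mu[g] = Binv @ E
        resid = np.linalg.norm(A @ mu[g] - E) / np.linalg.norm(E)
        if resid > 1e-8:
            raise NumericalError(
                f"solve residual {resid:.2e} at {nu} cm^-1 exceeds 1e-8"
            )
        tr[g] = np.sum(Binv[:q, :q] * uu)
    return FullSolveResult(grid=grid, B=B, mu=mu, trace_dispersive=tr, q=q)
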