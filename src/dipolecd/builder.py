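"""Idealized peptide-chain construction and secondary-structure rebuilds.

Chains are grown atom by atom with the natural-extension reference frame
(NeRF) construction: each new atom is placed from three predecessors with
an ideal bond length, ideal bond angle, and a torsion.  Backbone torsions
(phi, psi, omega) are the user's input -- or, for a rebuild, are measured
from an existing structure -- while bond lengths and angles always come
from the ideal-geometry table.  This deliberately discards the slightly
compressed bond lengths typical of crystal structures, to which the dipole
interaction model is very sensitive.

The rebuild route keeps only user-designated secondary-structure fragments;
if collisions (or the plan itself) would discard more than half of the
protein, the rebuild is declared a failure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import DipoleCDError, RebuildFailureError
from .structure import Atom, Chain, ProteinStructure, Residue

#: ideal backbone internal coordinates: bond lengths (A) and angles (deg)
IDEAL_GEOMETRY = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C-O": 1.231,
    "CA-CB": 1.521,
    "N-H": 1.010,
    "CA-HA": 1.090,
    "CB-HB": 1.090,
    "C-N-CA": 121.7,
    "N-CA-C": 111.2,
    "CA-C-N": 116.2,
    "CA-C-O": 120.8,
    "N-CA-CB": 110.4,
    "CA-CB-HB": 109.5,
}


@dataclass
class ChainRecipe:
    """Sequence plus per-residue (phi, psi, omega) torsions in degrees.

    omega is the torsion of the bond *preceding* each residue (undefined
    and ignored for the first); phi of the first residue and psi-dependent
    placements of the last are handled internally.
    """

    sequence: list[str]
    torsions: list[tuple[float, float, float]]
    ideal_geometry: dict = field(default_factory=lambda: dict(IDEAL_GEOMETRY))
    chain_id: str = "A"

    def __post_init__(self):
        if len(self.torsions) != len(self.sequence):
            raise DipoleCDError(
                f"torsion list length {len(self.torsions)} does not match "
                f"sequence length {len(self.sequence)}"
            )


def helix_recipe(n_residues: int, phi: float = -57.0, psi: float = -47.0,
                 sequence: list[str] | None = None) -> ChainRecipe:
    """Uniform-torsion recipe; the defaults are the ideal alpha-helix."""
    seq = sequence or ["ALA"] * n_residues
    return ChainRecipe(sequence=list(seq),
                       torsions=[(phi, psi, 180.0)] * n_residues)


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d given predecessors a-b-c, |cd|, angle(b,c,d), torsion(a,b,c,d)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def _tetrahedral_dirs(center, n1, n2):
    """The two free tetrahedral directions at ``center`` bonded to n1, n2."""
    d1 = (n1 - center) / np.linalg.norm(n1 - center)
    d2 = (n2 - center) / np.linalg.norm(n2 - center)
    bis = -(d1 + d2)
    bis = bis / np.linalg.norm(bis)
    perp = np.cross(d2, d1)
    perp = perp / np.linalg.norm(perp)
    half = math.radians(54.75)  # half the H-C-H tetrahedral opening
    u1 = math.cos(half) * bis + math.sin(half) * perp
    u2 = math.cos(half) * bis - math.sin(half) * perp
    return u1, u2


def build_chain(recipe: ChainRecipe, include_hydrogens: bool = False) -> ProteinStructure:
    """Cartesian coordinates from torsions and ideal internal coordinates.

    Seed frame: first N at the origin, first CA on +x, first C' in the
    xy-plane.  Every bond length and angle matches the ideal table exactly;
    measured torsions round-trip to the inputs.  C-beta is placed with
    L-amino-acid chirality; hydrogens (amide H, HA, methyl HB on alanine)
    are added at ideal positions on request.
    """
    g = recipe.ideal_geometry
    nres = len(recipe.sequence)
    if nres == 0:
        raise DipoleCDError("empty sequence")

    N = [None] * nres
    CA = [None] * nres
    C = [None] * nres

    N[0] = np.zeros(3)
    CA[0] = np.array([g["N-CA"], 0.0, 0.0])
    ang = math.radians(g["N-CA-C"])
    C[0] = CA[0] + g["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, nres):
        phi, _, omega = recipe.torsions[i]
        _, psi_prev, _ = recipe.torsions[i - 1]
        N[i] = nerf(N[i - 1], CA[i - 1], C[i - 1],
                    g["C-N"], g["CA-C-N"], psi_prev)
        CA[i] = nerf(CA[i - 1], C[i - 1], N[i],
                     g["N-CA"], g["C-N-CA"], omega)
        C[i] = nerf(C[i - 1], N[i], CA[i],
                    g["CA-C"], g["N-CA-C"], phi)

    chain = Chain(chain_id=recipe.chain_id)
    for i, resname in enumerate(recipe.sequence):
        res = Residue(name=resname, index=i + 1, chain_id=recipe.chain_id)

        def add(name, element, pos):
            res.atoms.append(Atom(name=name, element=element,
                                  residue_index=i + 1, residue_name=resname,
                                  chain_id=recipe.chain_id, position=pos))

        add("N", "N", N[i])
        add("CA", "C", CA[i])
        add("C", "C", C[i])
        # carbonyl O: anti-periplanar to the next N (torsion psi + 180)
        psi = recipe.torsions[i][1]
        add("O", "O", nerf(N[i], CA[i], C[i], g["C-O"], g["CA-C-O"],
                           psi + 180.0))
        has_cb = resname != "GLY"
        CB = None
        if has_cb:
            u1, u2 = _tetrahedral_dirs(CA[i], N[i], C[i])
            # L-chirality: CB on the side giving improper(N,C,CA,CB) < 0
            CB = CA[i] + g["CA-CB"] * u1
            if dihedral(N[i], C[i], CA[i], CB) > 0:
                CB = CA[i] + g["CA-CB"] * u2
                u1, u2 = u2, u1
            add("CB", "C", CB)
        if include_hydrogens:
            if i > 0 and resname != "PRO":
                d1 = (C[i - 1] - N[i]) / np.linalg.norm(C[i - 1] - N[i])
                d2 = (CA[i] - N[i]) / np.linalg.norm(CA[i] - N[i])
                hdir = -(d1 + d2)
                add("H", "H", N[i] + g["N-H"] * hdir / np.linalg.norm(hdir))
            if has_cb:
                add("HA", "H", CA[i] + g["CA-HA"] * u2)
                for k, tor in enumerate((60.0, 180.0, 300.0)):
                    add(f"HB{k + 1}", "H",
                        nerf(N[i], CA[i], CB, g["CB-HB"], g["CA-CB-HB"], tor))
            else:
                u1, u2 = _tetrahedral_dirs(CA[i], N[i], C[i])
                add("HA2", "H", CA[i] + g["CA-HA"] * u1)
                add("HA3", "H", CA[i] + g["CA-HA"] * u2)
        chain.residues.append(res)
    return ProteinStructure(chains=[chain])


def measure_torsions(structure: ProteinStructure) -> list[list[tuple]]:
    """Per-chain (phi, psi, omega) in degrees; NaN where undefined."""
    out = []
    for chain in structure.chains:
        rows = []
        res = chain.residues
        for i, r in enumerate(res):
            n, ca, c = (r.require("N").position, r.require("CA").position,
                        r.require("C").position)
            phi = psi = omega = float("nan")
            if i > 0:
                cp = res[i - 1].require("C").position
                cap = res[i - 1].require("CA").position
                phi = dihedral(cp, n, ca, c)
                omega = dihedral(cap, cp, n, ca)
            if i + 1 < len(res):
                nn = res[i + 1].require("N").position
                psi = dihedral(n, ca, c, nn)
            rows.append((phi, psi, omega))
        out.append(rows)
    return out


@dataclass
class FragmentPlan:
    """Kept secondary-structure fragments: (chain_id, first, last, label)."""

    fragments: list[tuple[str, int, int, str]]
    ignored: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self):
        spans: dict[str, list[tuple[int, int]]] = {}
        for cid, lo, hi, _ in self.fragments:
            if hi < lo:
                raise DipoleCDError(f"fragment range {lo}-{hi} is reversed")
            for a, b in spans.get(cid, []):
                if lo <= b and a <= hi:
                    raise DipoleCDError(
                        f"overlapping fragments in chain {cid}: "
                        f"{a}-{b} and {lo}-{hi}"
                    )
            spans.setdefault(cid, []).append((lo, hi))


def detect_collisions(structure: ProteinStructure, cutoff: float) -> list[tuple[Atom, Atom]]:
    """Non-bonded heavy-atom pairs closer than ``cutoff`` Angstrom.

    Pairs within one residue or between sequence-adjacent residues of the
    same chain are covalently connected and excluded.
    """
    if cutoff <= 0:
        return []
    atoms = [a for a in structure.iter_atoms() if not a.is_hydrogen]
    if len(atoms) < 2:
        return []
    pos = np.array([a.position for a in atoms])
    tree = cKDTree(pos)
    pairs = []
    for i, j in tree.query_pairs(cutoff):
        a, b = atoms[i], atoms[j]
        if a.chain_id == b.chain_id and abs(a.residue_index - b.residue_index) <= 1:
            continue
        pairs.append((a, b))
    return pairs


def rebuild_from_structure(
    structure: ProteinStructure,
    plan: FragmentPlan,
    ideal_geometry: dict | None = None,
    idealize_omega: bool = False,
    collision_cutoff: float = 2.0,
) -> ProteinStructure:
    """Rebuild kept fragments with ideal geometry and measured torsions.

    Residues not in the plan are dropped; non-aliphatic residues are mutated
    to alanine first; each fragment becomes its own chain (so no amide is
    ever created across fragments).  Fragments that collide after the
    rebuild are discarded; if discarded plus planned-ignored residues exceed
    50% of the protein, the rebuild is a failure.
    """
    from .structure import alanize  # deferred to avoid cycle at import time

    structure = alanize(structure)
    geometry = dict(IDEAL_GEOMETRY)
    if ideal_geometry:
        geometry.update(ideal_geometry)
    total = structure.p
    torsions_by_chain = {
        chain.chain_id: rows
        for chain, rows in zip(structure.chains, measure_torsions(structure))
    }
    res_by_chain = {c.chain_id: {r.index: i for i, r in enumerate(c.residues)}
                    for c in structure.chains}
    chain_by_id = {c.chain_id: c for c in structure.chains}

    built_fragments = []
    kept = 0
    for fi, (cid, lo, hi, label) in enumerate(plan.fragments):
        if cid not in chain_by_id:
            raise DipoleCDError(f"fragment chain {cid!r} not in structure")
        index_map = res_by_chain[cid]
        missing = [r for r in range(lo, hi + 1) if r not in index_map]
        if missing:
            raise DipoleCDError(
                f"fragment {cid}:{lo}-{hi} references missing residues {missing}"
            )
        rows = torsions_by_chain[cid]
        seq, tors = [], []
        for resnum in range(lo, hi + 1):
            i = index_map[resnum]
            phi, psi, omega = rows[i]
            if math.isnan(phi):
                phi = -57.0   # fragment start: phi is unused by the builder
            if math.isnan(psi):
                psi = -47.0   # chain end: only positions the final carbonyl O
            if math.isnan(omega) or idealize_omega:
                omega = 180.0
            seq.append(chain_by_id[cid].residues[i].name)
            tors.append((phi, psi, omega))
        frag = build_chain(
            ChainRecipe(sequence=seq, torsions=tors, ideal_geometry=geometry,
                        chain_id=f"{fi}"),
            include_hydrogens=True,
        )
        # renumber to the original residue numbers
        for res in frag.chains[0].residues:
            shift = lo - 1
            res.index += shift
            for a in res.atoms:
                a.residue_index += shift
        built_fragments.append((fi, cid, lo, hi, label, frag.chains[0]))
        kept += hi - lo + 1

    dropped = total - kept
    surviving = []
    for fi, cid, lo, hi, label, chain in built_fragments:
        probe = ProteinStructure(chains=[chain])
        if detect_collisions(probe, collision_cutoff):
            dropped += hi - lo + 1
        else:
            surviving.append(chain)
    if total and dropped / total > 0.5:
        raise RebuildFailureError(
            f"{dropped} of {total} residues ignored "
            f"({100 * dropped / total:.0f}% > 50%): rebuild failed"
        )
    if not surviving:
        raise RebuildFailureError("no fragments survived the rebuild")
    return ProteinStructure(chains=surviving)


def fit_helix_axis(ca_positions: np.ndarray) -> tuple[np.ndarray, float]:
    """Helix axis direction and mean rise per residue from CA coordinates.

    Uses second differences of the CA trace: for a regular helix the
    vectors w_i = v_{i+1} - v_i (v_i successive CA-CA bonds) are chords of a
    circle perpendicular to the axis, so successive cross products
    w_i x w_{i+1} all point along the axis.  The rise is the mean projection
    of v_i on that axis.  Independent of any internal-coordinate machinery.
    """
    ca = np.asarray(ca_positions, float)
    if len(ca) < 4:
        raise DipoleCDError("need at least 4 CA positions to fit a helix axis")
    v = np.diff(ca, axis=0)
    w = np.diff(v, axis=0)
    axes = np.cross(w[:-1], w[1:])
    norms = np.linalg.norm(axes, axis=1)
    good = norms > 1e-12
    if not np.any(good):
        raise DipoleCDError("degenerate CA trace: no helix axis")
    axis = np.sum(axes[good] / norms[good, None], axis=0)
    axis = axis / np.linalg.norm(axis)
    rise = float(np.mean(v @ axis))
    if rise < 0:
        axis, rise = -axis, -rise
    return axis, rise
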