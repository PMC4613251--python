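"""PDB reading, atom classification, and the alanine reduction.

The model sees a protein as two populations of polarizable points: one
anisotropic point per peptide bond (built later from the N, C', O triad) and
one isotropic point per parameterized nonchromophoric atom (aliphatic
carbons, alcohol oxygens, hydrogens).  Everything else -- sulfurs, metals,
waters, terminal carboxylates -- is ignored, with the reason recorded.

Only aliphatic residues (ALA, VAL, PRO, GLY, LEU, ILE) are treated in full;
:func:`alanize` truncates every other residue at C-beta and renames it ALA,
which perturbs neither the backbone nor the amide chromophores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import EmptyStructureError, FormatError, MissingAtomError

#: residues treated in their entirety; all others are mutated to ALA
ALIPHATIC_RESIDUES = frozenset({"ALA", "VAL", "PRO", "GLY", "LEU", "ILE"})

#: maximum C'-N distance (A) for two consecutive residues to share a peptide bond
PEPTIDE_BOND_CUTOFF = 2.0

#: geometric connectivity cutoffs (A) used for methyl detection and H parents
H_BOND_CUTOFF = 1.2
HEAVY_BOND_CUTOFF = 1.8


@dataclass
class Atom:
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise FormatError(f"non-finite coordinates for atom {self.name}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Residue:
    name: str
    index: int
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def require(self, name: str) -> Atom:
        a = self.atom(name)
        if a is None:
            raise MissingAtomError(
                f"residue {self.name} {self.chain_id}{self.index} lacks "
                f"backbone atom {name}"
            )
        return a


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class ProteinStructure:
    chains: list[Chain] = field(default_factory=list)

    @property
    def p(self) -> int:
        """Total number of peptide residues."""
        return sum(len(c.residues) for c in self.chains)

    def iter_residues(self):
        for chain in self.chains:
            yield from chain.residues

    def iter_atoms(self):
        for res in self.iter_residues():
            yield from res.atoms


@dataclass
class AmideTriad:
    """The (N, C', O) atoms of one peptide bond, spanning residues i/i+1."""

    n: Atom       # amide nitrogen of residue i+1
    c: Atom       # carbonyl carbon of residue i
    o: Atom       # carbonyl oxygen of residue i
    chain_id: str
    residue_index: int  # index of the C'-side residue


@dataclass
class UnitClassification:
    amide_triads: list[AmideTriad]
    isotropic_atoms: list[tuple[Atom, str]]     # (atom, species)
    ignored_atoms: list[tuple[Atom, str]]       # (atom, reason)
    p: int

    @property
    def q(self) -> int:
        return len(self.amide_triads)


def _element_of(name: str, element_hint: str = "") -> str:
    if element_hint:
        return element_hint.strip().capitalize()
    # classify by the first alphabetic character: handles both HB1 and 1HB
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.altloc or "~"))
        kept.append(best)
    return kept


def read_pdb(path: str | Path, model_index: int = 1) -> ProteinStructure:
    """Read one model of a PDB file into a :class:`ProteinStructure`.

    HETATM records are excluded; alternative conformations are resolved to
    the highest-occupancy (ties: alphabetically first) altloc.  Every residue
    must carry the N, CA, C, O backbone atoms.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}")
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no models")
    if not 1 <= model_index <= len(st):
        raise FormatError(
            f"model_index {model_index} out of range (file has {len(st)} models)"
        )
    model = st[model_index - 1]

    structure = ProteinStructure()
    for gchain in model:
        chain = Chain(chain_id=gchain.name.strip() or "A")
        for gres in gchain:
            if gres.het_flag == "H":
                continue  # HETATM: ligands, waters, metals
            atoms = []
            for gatom in gres:
                atoms.append(
                    Atom(
                        name=gatom.name.strip(),
                        element=_element_of(gatom.name.strip(), gatom.element.name),
                        residue_index=gres.seqid.num,
                        residue_name=gres.name.strip(),
                        chain_id=chain.chain_id,
                        position=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        occupancy=gatom.occ,
                        altloc=gatom.altloc.strip(),
                    )
                )
            if atoms:
                chain.residues.append(
                    Residue(
                        name=gres.name.strip(),
                        index=gres.seqid.num,
                        chain_id=chain.chain_id,
                        atoms=_resolve_altlocs(atoms),
                    )
                )
        if chain.residues:
            structure.chains.append(chain)

    if structure.p == 0:
        raise EmptyStructureError(f"{path} contains no ATOM records")
    for res in structure.iter_residues():
        for backbone in ("N", "CA", "C", "O"):
            res.require(backbone)
    return structure


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write a structure as minimal PDB ATOM/TER/END records."""
    lines = []
    serial = 0
    for chain in structure.chains:
        for res in chain.residues:
            for a in res.atoms:
                serial += 1
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{'':1s}{res.name:>3s} "
                    f"{chain.chain_id:1s}{res.index:4d}    "
                    f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                    f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
                )
        serial += 1
        lines.append(f"TER   {serial:5d}      {chain.residues[-1].name:>3s} "
                     f"{chain.chain_id:1s}{chain.residues[-1].index:4d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def alanize(structure: ProteinStructure) -> ProteinStructure:
    """Mutate every non-aliphatic residue to alanine.

    Side-chain atoms beyond C-beta are removed (hydrogens follow their
    nearest kept heavy atom); backbone and C-beta coordinates are untouched.
    Aliphatic residues pass through unchanged.
    """
    out = ProteinStructure()
    for chain in structure.chains:
        new_chain = Chain(chain_id=chain.chain_id)
        for res in chain.residues:
            if res.name in ALIPHATIC_RESIDUES:
                new_chain.residues.append(
                    Residue(res.name, res.index, res.chain_id, list(res.atoms))
                )
                continue
            keep_heavy_names = {"N", "CA", "C", "O", "OXT", "CB"}
            heavy_kept = [a for a in res.atoms
                          if not a.is_hydrogen and a.name in keep_heavy_names]
            heavy_all = [a for a in res.atoms if not a.is_hydrogen]
            kept = list(heavy_kept)
            for a in res.atoms:
                if not a.is_hydrogen:
                    continue
                parent = min(
                    heavy_all,
                    key=lambda h: float(np.linalg.norm(h.position - a.position)),
                    default=None,
                )
                if parent is not None and parent.name in keep_heavy_names:
                    kept.append(a)
            new_res = Residue("ALA", res.index, res.chain_id, [])
            for a in kept:
                new_res.atoms.append(
                    Atom(a.name, a.element, a.residue_index, "ALA",
                         a.chain_id, a.position.copy(), a.occupancy, a.altloc)
                )
            new_chain.residues.append(new_res)
        out.chains.append(new_chain)
    return out


def _methyl_carbons(structure: ProteinStructure) -> set[int]:
    """Identify CH3 carbons geometrically: 3 bonded H, 1 bonded heavy atom."""
    atoms = list(structure.iter_atoms())
    methyls: set[int] = set()
    positions = np.array([a.position for a in atoms])
    for i, a in enumerate(atoms):
        if a.element != "C":
            continue
        d = np.linalg.norm(positions - positions[i], axis=1)
        n_h = sum(
            1 for j, b in enumerate(atoms)
            if j != i and b.is_hydrogen and d[j] < H_BOND_CUTOFF
        )
        n_heavy = sum(
            1 for j, b in enumerate(atoms)
            if j != i and not b.is_hydrogen and d[j] < HEAVY_BOND_CUTOFF
        )
        if n_h == 3 and n_heavy == 1:
            methyls.add(id(a))
    return methyls


def classify_units(
    structure: ProteinStructure,
    include_hydrogens: bool = False,
    drop_methyl_hydrogens: bool = True,
) -> UnitClassification:
    """Partition all atoms into amide triads, isotropic points, and ignored.

    One triad is created per peptide bond: residues adjacent in sequence
    (consecutive numbering, same chain) whose C'-N distance is below
    2.0 A.  A single unbroken chain of p residues therefore yields q = p - 1
    triads; chain breaks split the count per fragment, and bonds are never
    created across chains.
    """
    if all(len(c.residues) < 2 for c in structure.chains):
        raise MissingAtomError("structure has no chain with >= 2 residues")

    triads: list[AmideTriad] = []
    triad_atom_ids: set[int] = set()
    for chain in structure.chains:
        for r1, r2 in zip(chain.residues, chain.residues[1:]):
            if r2.index - r1.index != 1:
                continue  # numbering gap: chain break
            c = r1.require("C")
            o = r1.require("O")
            n = r2.require("N")
            if np.linalg.norm(n.position - c.position) >= PEPTIDE_BOND_CUTOFF:
                continue  # geometric break
            triads.append(AmideTriad(n=n, c=c, o=o, chain_id=chain.chain_id,
                                     residue_index=r1.index))
            triad_atom_ids.update((id(n), id(c), id(o)))

    methyls = _methyl_carbons(structure) if (include_hydrogens and
                                             drop_methyl_hydrogens) else set()
    heavy_atoms = [a for a in structure.iter_atoms() if not a.is_hydrogen]
    heavy_pos = np.array([a.position for a in heavy_atoms])

    isotropic: list[tuple[Atom, str]] = []
    ignored: list[tuple[Atom, str]] = []
    for atom in structure.iter_atoms():
        if id(atom) in triad_atom_ids:
            continue  # belongs to a chromophore point
        el = atom.element
        if el == "C":
            if atom.name == "C":
                ignored.append((atom, "terminal carbonyl carbon"))
            else:
                isotropic.append((atom, "C_aliphatic"))
        elif el == "O":
            if atom.name == "O":
                ignored.append((atom, "terminal carbonyl oxygen"))
            elif atom.name == "OXT":
                ignored.append((atom, "terminal carboxylate oxygen"))
            else:
                isotropic.append((atom, "O_alcohol"))
        elif el == "N":
            ignored.append((atom, "free amine nitrogen (no amide partner)"))
        elif el == "H":
            if not include_hydrogens:
                ignored.append((atom, "hydrogens excluded"))
                continue
            if len(heavy_atoms) == 0:
                ignored.append((atom, "no heavy atom to attach to"))
                continue
            d = np.linalg.norm(heavy_pos - atom.position, axis=1)
            parent = heavy_atoms[int(np.argmin(d))]
            if parent.element == "C":
                if id(parent) in methyls:
                    ignored.append((atom, "methyl hydrogen"))
                else:
                    isotropic.append((atom, "H_aliphatic"))
            elif parent.element == "O":
                isotropic.append((atom, "H_alcohol"))
            elif parent.element == "N":
                isotropic.append((atom, "H_amide"))
            else:
                ignored.append((atom, f"hydrogen on unparameterized {parent.element}"))
        else:
            ignored.append((atom, f"no polarizability parameter for element {el}"))

    return UnitClassification(
        amide_triads=triads,
        isotropic_atoms=isotropic,
        ignored_atoms=ignored,
        p=structure.p,
    )


def write_classification_report(
    classification: UnitClassification, path: str | Path
) -> None:
    """Write the atom-by-atom classification as TSV (atom, category, detail)."""
    lines = ["atom\tcategory\tdetail"]
    for t in classification.amide_triads:
        for role, a in (("N", t.n), ("C'", t.c), ("O", t.o)):
            lines.append(
                f"{a.chain_id}/{a.residue_index}/{a.name}\tchromophore\t"
                f"amide {t.chain_id}{t.residue_index} ({role})"
            )
    for a, species in classification.isotropic_atoms:
        lines.append(f"{a.chain_id}/{a.residue_index}/{a.name}\tisotropic\t{species}")
    for a, reason in classification.ignored_atoms:
        lines.append(f"{a.chain_id}/{a.residue_index}/{a.name}\tignored\t{reason}")
    Path(path).write_text("\n".join(lines) + "\n")
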