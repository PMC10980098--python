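"""PDB-backed data model for two-chain protein-peptide complexes.

The unit of analysis throughout the package is a :class:`ComplexStructure`:
one "target" protein chain and one peptide chain, each an ordered list of
residues carrying heavy atoms with Cartesian coordinates in Angstroms and
van der Waals radii. Parsing keeps only ATOM records (no HETATM, waters or
hydrogens), resolves alternate locations to the highest-occupancy copy, and
reads the first model of multi-MODEL files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .errors import MissingChainError, PDBParseError

__all__ = [
    "Atom3D",
    "ResidueRecord",
    "ComplexStructure",
    "RadiiTable",
    "DEFAULT_RADII",
    "parse_pdb",
    "write_pdb",
    "min_residue_distance",
]

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1_TO_3 = {v: k for k, v in _AA3_TO_1.items()}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class Atom3D:
    """One heavy atom: PDB name, element symbol, position (Å), vdW radius (Å)."""

    name: str
    element: str
    position: np.ndarray
    vdw_radius: float

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.vdw_radius > 0:
            raise ValueError(f"atom {self.name!r}: vdw_radius must be positive")


@dataclass(frozen=True)
class ResidueRecord:
    """A residue: chain ID, PDB residue number (+ insertion code), name, atoms."""

    chain_id: str
    seq_index: int
    res_name: str
    atoms: tuple[Atom3D, ...]
    ins_code: str = ""

    def __post_init__(self):
        if len(self.atoms) == 0:
            raise ValueError(
                f"residue {self.res_name} {self.seq_index}{self.ins_code} has no atoms"
            )
        object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def one_letter(self) -> str:
        return _AA3_TO_1.get(self.res_name, "X")

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array."""
        return np.array([a.position for a in self.atoms])

    def atom(self, name: str) -> Atom3D | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass(frozen=True)
class ComplexStructure:
    """A protein chain and a peptide chain, each ordered by residue number."""

    protein: tuple[ResidueRecord, ...]
    peptide: tuple[ResidueRecord, ...]
    source_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "protein", tuple(self.protein))
        object.__setattr__(self, "peptide", tuple(self.peptide))
        if not self.protein or not self.peptide:
            raise ValueError("both chains must be non-empty")
        pc = {r.chain_id for r in self.protein}
        qc = {r.chain_id for r in self.peptide}
        if len(pc) != 1 or len(qc) != 1:
            raise ValueError("each chain must carry a single chain ID")
        if pc == qc:
            raise ValueError("protein and peptide chain IDs must differ")
        for chain in (self.protein, self.peptide):
            keys = [(r.seq_index, r.ins_code) for r in chain]
            if any(b <= a for a, b in zip(keys, keys[1:])):
                raise ValueError("residue numbering must be strictly increasing")

    @property
    def protein_chain_id(self) -> str:
        return self.protein[0].chain_id

    @property
    def peptide_chain_id(self) -> str:
        return self.peptide[0].chain_id

    @property
    def peptide_sequence(self) -> str:
        return "".join(r.one_letter for r in self.peptide)

    @property
    def protein_sequence(self) -> str:
        return "".join(r.one_letter for r in self.protein)

    def chain(self, side: str) -> tuple[ResidueRecord, ...]:
        if side == "protein":
            return self.protein
        if side == "peptide":
            return self.peptide
        raise ValueError(f"side must be 'protein' or 'peptide', got {side!r}")

    def all_atoms(self) -> list[Atom3D]:
        out: list[Atom3D] = []
        for res in self.protein + self.peptide:
            out.extend(res.atoms)
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ComplexStructure":
        """Rigid-body copy: x -> R x + t applied to every atom of both chains."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)

        def _move(res: ResidueRecord) -> ResidueRecord:
            atoms = tuple(
                replace(a, position=rotation @ a.position + translation) for a in res.atoms
            )
            return replace(res, atoms=atoms)

        return ComplexStructure(
            protein=tuple(_move(r) for r in self.protein),
            peptide=tuple(_move(r) for r in self.peptide),
            source_id=self.source_id,
        )


@dataclass(frozen=True)
class RadiiTable:
    """Element -> van der Waals radius (Å), with a default for unknown elements.

    Bondi-style heavy-atom values; the solvent probe is added separately by
    the SASA routine.
    """

    radii: dict = field(
        default_factory=lambda: {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
    )
    default: float = 1.70

    def __post_init__(self):
        for el, r in {**self.radii, "default": self.default}.items():
            if not (0.5 < r < 3.0):
                raise ValueError(f"radius for {el!r} out of the plausible (0.5, 3.0) Å range")

    def lookup(self, element: str) -> float:
        return self.radii.get(element.upper(), self.default)


DEFAULT_RADII = RadiiTable()


def _guess_element(atom_name: str, raw_element: str) -> str:
    el = raw_element.strip()
    if el:
        return el.upper()
    # Fall back to the first alphabetic character of the atom name.
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "C"


def parse_pdb(
    text: str,
    protein_chain: str,
    peptide_chain: str,
    radii: RadiiTable = DEFAULT_RADII,
    source_id: str = "",
) -> ComplexStructure:
    """Parse fixed-width PDB text into a two-chain :class:`ComplexStructure`.

    Only ATOM records of the two requested chains are kept; HETATM records,
    waters and hydrogens are dropped. Alternate locations are resolved to the
    highest occupancy (ties keep the first encountered). Only the first model
    of a multi-MODEL file is read.

    Raises
    ------
    MissingChainError
        If a requested chain has no ATOM records.
    PDBParseError
        If an ATOM line has malformed numeric fields (reports line number).
    """
    if protein_chain == peptide_chain:
        raise ValueError("protein and peptide chains must differ")
    wanted = {protein_chain, peptide_chain}
    # residue key -> atom name -> (occupancy, Atom3D); insertion order kept
    chains: dict[str, dict] = {protein_chain: {}, peptide_chain: {}}

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("ENDMDL"):
            break  # first model only
        if not rec.startswith("ATOM"):
            continue
        if len(line) < 54:
            raise PDBParseError("ATOM record shorter than coordinate fields", lineno)
        chain_id = line[21]
        if chain_id not in wanted:
            continue
        res_name = line[17:20].strip()
        if res_name in _WATER_NAMES:
            continue
        atom_name = line[12:16]
        element = _guess_element(atom_name, line[76:78] if len(line) >= 78 else "")
        if element == "H" or element == "D":
            continue
        try:
            seq_index = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(f"malformed ATOM numeric field ({exc})", lineno) from None
        occ_field = line[54:60].strip() if len(line) > 54 else ""
        try:
            occupancy = float(occ_field) if occ_field else 1.0
        except ValueError:
            raise PDBParseError("malformed occupancy field", lineno) from None
        ins_code = line[26].strip()
        atom = Atom3D(
            name=atom_name.strip(),
            element=element,
            position=np.array([x, y, z]),
            vdw_radius=radii.lookup(element),
        )
        res_key = (seq_index, ins_code)
        residue = chains[chain_id].setdefault(res_key, {"res_name": res_name, "atoms": {}})
        key = atom.name
        prev = residue["atoms"].get(key)
        if prev is None or occupancy > prev[0]:
            # altloc resolution: keep highest occupancy, first encountered on ties
            residue["atoms"][key] = (occupancy, atom)

    def _build(chain_id: str) -> tuple[ResidueRecord, ...]:
        res_map = chains[chain_id]
        if not res_map:
            raise MissingChainError(chain_id)
        out = []
        for (seq_index, ins_code) in sorted(res_map):
            entry = res_map[(seq_index, ins_code)]
            atoms = tuple(a for _, a in entry["atoms"].values())
            out.append(
                ResidueRecord(
                    chain_id=chain_id,
                    seq_index=seq_index,
                    ins_code=ins_code,
                    res_name=entry["res_name"],
                    atoms=atoms,
                )
            )
        return tuple(out)

    return ComplexStructure(
        protein=_build(protein_chain),
        peptide=_build(peptide_chain),
        source_id=source_id,
    )


def _format_atom_name(name: str, element: str) -> str:
    # PDB convention: one/two-letter elements right-align differently in cols 13-16
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(complex: ComplexStructure) -> str:
    """Serialize a complex to fixed-width PDB ATOM records (3-decimal coords).

    ``parse_pdb(write_pdb(c))`` reproduces atoms, names and coordinates to
    the PDB precision of 3 decimals.
    """
    lines = []
    serial = 0
    for chain in (complex.protein, complex.peptide):
        for res in chain:
            if res.seq_index > 9999 or res.seq_index < -999:
                raise ValueError(
                    f"residue number {res.seq_index} does not fit the PDB fixed-width field"
                )
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.position
                if any(abs(v) >= 10000 for v in (x, y, z)):
                    raise ValueError("coordinate does not fit the 8.3 PDB field")
                lines.append(
                    f"ATOM  {serial:>5d} {_format_atom_name(atom.name, atom.element)}"
                    f" {res.res_name:<3s} {res.chain_id}{res.seq_index:>4d}{res.ins_code or ' '}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def min_residue_distance(a: ResidueRecord, b: ResidueRecord) -> float:
    """Minimum Euclidean distance (Å) over all heavy-atom pairs of two residues."""
    return float(cdist(a.coords(), b.coords()).min())


def one_to_three(aa: str) -> str:
    """One-letter amino-acid code to the PDB 3-letter residue name."""
    try:
        return _AA1_TO_3[aa.upper()]
    except KeyError:
        raise ValueError(f"unknown amino acid {aa!r}") from None


def three_to_one(res_name: str) -> str:
    return _AA3_TO_1.get(res_name.upper(), "X")
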