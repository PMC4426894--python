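"""Read protein structures and secondary-structure labels.

Produces per-chain residue lists carrying N-Ca-C backbone triplets together
with NAD/FAD heteroatom groups, plus readers for the classic DSSP flat format
and a dihedral-window fallback secondary-structure assigner for when no DSSP
output is available.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

from ._geometry import dihedral
from .errors import (
    DsspFormatError,
    EmptyChainError,
    PdbParseError,
    SecondaryStructureMismatchError,
)

logger = logging.getLogger(__name__)

SUPPORTED_LIGANDS = frozenset({"NAD", "FAD"})

#: 3-letter -> 1-letter codes for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Common nonstandard residues mapped to their parent amino acid.
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "CSO": "CYS", "SEP": "SER", "TPO": "THR", "PTR": "TYR",
    "MLY": "LYS", "CME": "CYS", "KCX": "LYS", "LLP": "LYS",
}

DSSP_STATES = frozenset("HGIEBTS-")


@dataclass
class AtomRecord:
    """One atom: PDB atom name, element, coordinates, occupancy, alt-loc."""

    atom_name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    alt_loc: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")


@dataclass
class Triplet:
    """Ordered N-Ca-C backbone coordinates of one residue."""

    n_coord: np.ndarray
    ca_coord: np.ndarray
    c_coord: np.ndarray

    def __post_init__(self):
        self.n_coord = np.asarray(self.n_coord, dtype=float)
        self.ca_coord = np.asarray(self.ca_coord, dtype=float)
        self.c_coord = np.asarray(self.c_coord, dtype=float)
        for d, name in ((self.bond_n_ca, "N-CA"), (self.bond_ca_c, "CA-C")):
            if not (1.0 < d < 2.5):
                warnings.warn(
                    f"unusual {name} bond length {d:.2f} A in triplet",
                    stacklevel=2,
                )

    @property
    def bond_n_ca(self) -> float:
        return float(np.linalg.norm(self.n_coord - self.ca_coord))

    @property
    def bond_ca_c(self) -> float:
        return float(np.linalg.norm(self.ca_coord - self.c_coord))

    @property
    def coords(self) -> np.ndarray:
        """(3, 3) array of N, Ca, C coordinates in order."""
        return np.stack([self.n_coord, self.ca_coord, self.c_coord])

    def __eq__(self, other):
        if not isinstance(other, Triplet):
            return NotImplemented
        return bool(np.array_equal(self.coords, other.coords))


@dataclass(eq=False)
class ResidueUnit:
    """One residue of a chain, with its backbone triplet when complete."""

    chain_id: str
    seq_pos: int | str
    res_name: str
    triplet: Triplet | None = None
    ss_label: str = "-"
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def is_standard(self) -> bool:
        return self.res_name in THREE_TO_ONE

    @property
    def one_letter(self) -> str | None:
        return THREE_TO_ONE.get(self.res_name)

    def atom_coords(self) -> np.ndarray:
        return np.stack([a.coords for a in self.atoms])


@dataclass(eq=False)
class LigandInstance:
    """A bound NAD/FAD molecule (one HETATM residue group)."""

    ligand_code: str
    chain_id: str
    het_seq: int
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.ligand_code not in SUPPORTED_LIGANDS:
            raise ValueError(f"unsupported ligand code {self.ligand_code!r}")
        if not self.atoms:
            raise ValueError("ligand must have at least one atom")

    def atom_coords(self) -> np.ndarray:
        return np.stack([a.coords for a in self.atoms])


@dataclass(eq=False)
class StructureModel:
    """First-model view of one PDB entry: chains of residues plus ligands."""

    pdb_id: str
    chains: dict[str, list[ResidueUnit]] = field(default_factory=dict)
    ligands: list[LigandInstance] = field(default_factory=list)

    def residue_index(self) -> dict[tuple[str, int | str], ResidueUnit]:
        out = {}
        for cid, residues in self.chains.items():
            for r in residues:
                out[(cid, r.seq_pos)] = r
        return out


def _seq_pos(resseq: int, icode: str) -> int | str:
    icode = icode.strip()
    return resseq if not icode else f"{resseq}{icode}"


def _resolve_atom(atom):
    """Pick one location for a possibly disordered atom.

    Highest occupancy wins; ties broken by alphabetical alt-loc.
    """
    if atom.is_disordered():
        children = atom.disordered_get_list()
        best = sorted(children, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))[0]
        return best
    return atom


def _atom_record(atom) -> AtomRecord:
    return AtomRecord(
        atom_name=atom.get_name(),
        element=(atom.element or "").strip(),
        coords=np.array(atom.get_coord(), dtype=float),
        occupancy=float(atom.get_occupancy() or 1.0),
        alt_loc=atom.get_altloc().strip(),
    )


def parse_pdb_chains(
    pdb_text: str,
    model_policy: str = "first_model",
    pdb_id: str | None = None,
) -> StructureModel:
    """Parse PDB text into a :class:`StructureModel`.

    Only the first MODEL of multi-model files is read. Alt-locs are resolved
    to the highest-occupancy conformer (ties alphabetical). HETATM groups
    named NAD or FAD become :class:`LigandInstance` objects; waters are
    skipped. Residues missing any of N/CA/C are retained without a triplet
    and logged.
    """
    if model_policy != "first_model":
        raise ValueError(f"unknown model policy {model_policy!r}")
    if not any(line.startswith("ATOM") for line in pdb_text.splitlines()):
        raise PdbParseError("no ATOM records found in input")

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(pdb_id or "XXXX", io.StringIO(pdb_text))
    try:
        bio_model = next(iter(structure))
    except StopIteration:  # pragma: no cover - guarded by ATOM check above
        raise PdbParseError("no model found in input") from None

    if pdb_id is None:
        header_id = (structure.header or {}).get("idcode") or ""
        pdb_id = header_id.strip().lower() or "xxxx"

    model = StructureModel(pdb_id=pdb_id)
    for bio_chain in bio_model:
        chain_id = bio_chain.id
        residues: list[ResidueUnit] = []
        for bio_res in bio_chain:
            hetflag, resseq, icode = bio_res.id
            resname = bio_res.get_resname().strip()
            atoms = [_atom_record(_resolve_atom(a)) for a in bio_res.get_list()]
            if hetflag.strip():
                if hetflag == "W":
                    continue
                if resname in SUPPORTED_LIGANDS:
                    model.ligands.append(
                        LigandInstance(
                            ligand_code=resname,
                            chain_id=chain_id,
                            het_seq=int(resseq),
                            atoms=atoms,
                        )
                    )
                    continue
                # other hetero groups: fall through only if they are mapped
                # modified amino acids (e.g. MSE placed as HETATM)
                if resname not in NONSTANDARD_PARENT:
                    continue
            res_name = NONSTANDARD_PARENT.get(resname, resname)
            by_name = {a.atom_name: a for a in atoms}
            triplet = None
            if all(k in by_name for k in ("N", "CA", "C")):
                triplet = Triplet(
                    by_name["N"].coords, by_name["CA"].coords, by_name["C"].coords
                )
            else:
                logger.info(
                    "residue %s %s%s lacks complete backbone; excluded from alignment",
                    resname, chain_id, _seq_pos(resseq, icode),
                )
            residues.append(
                ResidueUnit(
                    chain_id=chain_id,
                    seq_pos=_seq_pos(resseq, icode),
                    res_name=res_name,
                    triplet=triplet,
                    atoms=atoms,
                )
            )
        if residues:
            model.chains[chain_id] = residues
    return model


def extract_triplets(chain: list[ResidueUnit]) -> list[Triplet]:
    """Triplets of the residues that have one, preserving sequence order."""
    if not chain:
        raise EmptyChainError("chain is empty")
    triplets = [r.triplet for r in chain if r.triplet is not None]
    if not triplets:
        raise EmptyChainError("no residue in chain has a complete backbone triplet")
    return triplets


def residues_with_triplets(chain: list[ResidueUnit]) -> list[ResidueUnit]:
    """The residues of a chain that carry a complete backbone triplet."""
    return [r for r in chain if r.triplet is not None]


# ---------------------------------------------------------------------------
# DSSP flat-file reading and fallback assignment
# ---------------------------------------------------------------------------

def read_dssp(dssp_text: str) -> list[tuple[str, int | str, str]]:
    """Parse classic DSSP output into (chain_id, seq_pos, ss_label) rows."""
    lines = dssp_text.splitlines()
    start = None
    for k, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = k + 1
            break
    if start is None:
        raise DsspFormatError('DSSP header line "  #  RESIDUE" not found')
    rows: list[tuple[str, int | str, str]] = []
    for line in lines[start:]:
        if len(line) < 17:
            continue
        if line[13] == "!":  # chain break
            continue
        try:
            resseq = int(line[5:10])
        except ValueError:
            continue
        icode = line[10]
        chain_id = line[11].strip() or " "
        ss = line[16]
        if ss == " ":
            ss = "-"
        elif ss not in DSSP_STATES:
            warnings.warn(f"unknown DSSP state {ss!r}; mapped to '-'", stacklevel=2)
            ss = "-"
        rows.append((chain_id, _seq_pos(resseq, icode), ss))
    return rows


# Dihedral windows of the fallback assigner (degrees).
_HELIX_PHI = (-77.0, -37.0)
_HELIX_PSI = (-67.0, -27.0)
_STRAND_PHI = (-149.0, -89.0)
_STRAND_PSI = (83.0, 143.0)


def _in_window(x: float | None, lo: float, hi: float) -> bool:
    return x is not None and lo < x < hi


def _chain_dihedrals(chain: list[ResidueUnit]):
    """phi/psi per residue (None where undefined)."""
    n = len(chain)
    phi = [None] * n
    psi = [None] * n
    for i, r in enumerate(chain):
        if r.triplet is None:
            continue
        if i > 0 and chain[i - 1].triplet is not None:
            prev = chain[i - 1].triplet
            phi[i] = dihedral(prev.c_coord, r.triplet.n_coord, r.triplet.ca_coord, r.triplet.c_coord)
        if i < n - 1 and chain[i + 1].triplet is not None:
            nxt = chain[i + 1].triplet
            psi[i] = dihedral(r.triplet.n_coord, r.triplet.ca_coord, r.triplet.c_coord, nxt.n_coord)
    return phi, psi


def _fallback_ss(chain: list[ResidueUnit]) -> list[str]:
    """Dihedral-window secondary structure: H / E / '-'.

    H requires >=3 consecutive residues inside the helix window, E requires
    >=2 consecutive residues inside the strand window.
    """
    phi, psi = _chain_dihedrals(chain)
    n = len(chain)
    q_h = [_in_window(phi[i], *_HELIX_PHI) and _in_window(psi[i], *_HELIX_PSI) for i in range(n)]
    q_e = [_in_window(phi[i], *_STRAND_PHI) and _in_window(psi[i], *_STRAND_PSI) for i in range(n)]
    labels = ["-"] * n
    for qualifies, label, min_run in ((q_e, "E", 2), (q_h, "H", 3)):
        i = 0
        while i < n:
            if not qualifies[i]:
                i += 1
                continue
            j = i
            while j < n and qualifies[j]:
                j += 1
            if j - i >= min_run:
                for k in range(i, j):
                    labels[k] = label
            i = j
    return labels


def assign_secondary_structure(
    model: StructureModel, dssp_text: str | None = None
) -> dict[tuple[str, int | str], str]:
    """Assign an 8-state SS label to every residue of the model.

    With ``dssp_text`` labels are read verbatim from the DSSP file; without
    it the dihedral-window fallback produces 3 states (H/E/-). Residues not
    covered get '-'. The assignment is also written onto each residue's
    ``ss_label``.
    """
    labels: dict[tuple[str, int | str], str] = {}
    index = model.residue_index()
    if dssp_text is not None:
        rows = read_dssp(dssp_text)
        missing = [(c, p) for c, p, _ in rows if (c, p) not in index]
        if missing:
            raise SecondaryStructureMismatchError(missing)
        for c, p, ss in rows:
            labels[(c, p)] = ss
    else:
        for chain_id, chain in model.chains.items():
            for r, ss in zip(chain, _fallback_ss(chain)):
                labels[(chain_id, r.seq_pos)] = ss
    for key, residue in index.items():
        residue.ss_label = labels.get(key, "-")
        labels.setdefault(key, "-")
    return labels


# ---------------------------------------------------------------------------
# PDB writing (synthetic fixtures, debugging)
# ---------------------------------------------------------------------------

def write_model_pdb(model: StructureModel) -> str:
    """Render a StructureModel as minimal standard PDB text."""
    lines = []
    serial = 1
    for chain_id, residues in model.chains.items():
        for r in residues:
            num, icode = _split_seq_pos(r.seq_pos)
            for a in r.atoms:
                lines.append(_pdb_atom_line("ATOM", serial, a, r.res_name, chain_id, num, icode))
                serial += 1
        lines.append(f"TER   {serial:>5}")
        serial += 1
    for lig in model.ligands:
        for a in lig.atoms:
            lines.append(
                _pdb_atom_line("HETATM", serial, a, lig.ligand_code, lig.chain_id, lig.het_seq, "")
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _split_seq_pos(seq_pos: int | str) -> tuple[int, str]:
    if isinstance(seq_pos, int):
        return seq_pos, ""
    return int(seq_pos[:-1]), seq_pos[-1]


def _pdb_atom_line(record, serial, atom: AtomRecord, resname, chain_id, resseq, icode):
    name = atom.atom_name
    # standard PDB alignment: 1-3 char names start in column 14
    name_field = f" {name:<3}" if len(name) < 4 else name
    x, y, z = atom.coords
    elem = (atom.element or name[0]).rjust(2)
    return (
        f"{record:<6}{serial:>5} {name_field}{'':1}{resname:<3} {chain_id}"
        f"{resseq:>4}{icode or ' ':1}   {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{atom.occupancy:6.2f}{0.0:6.2f}          {elem}"
    )
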