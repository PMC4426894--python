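"""Binding-residue template construction and serialization.

Bound NAD/FAD ligands are decomposed into three moieties (nicotinamide or
flavin, adenosine, phosphate). Residues in contact with a moiety become a
binding-residue template whenever the group holds at least two residues with
complete backbone triplets. Templates are serialized as versioned JSON lines.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import (
    EmptyChainError,
    MoietyPartitionError,
    TemplateDbFormatError,
    TemplateDbVersionError,
)
from .structure_io import (
    LigandInstance,
    ResidueUnit,
    StructureModel,
    Triplet,
)

logger = logging.getLogger(__name__)

DB_FORMAT = "fragsite-template-db"
DB_VERSION = 1

#: Moiety names per ligand kind, in canonical order.
MOIETY_ORDER = {
    "NAD": ("nicotinamide", "adenosine", "phosphate"),
    "FAD": ("flavin", "adenosine", "phosphate"),
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


def _load_moiety_tables() -> dict[str, dict[str, list[str]]]:
    text = resources.files("fragsite.data").joinpath("moieties.yaml").read_text()
    return yaml.safe_load(text)


MOIETY_ATOMS: dict[str, dict[str, list[str]]] = _load_moiety_tables()


@dataclass(eq=False)
class LigandMoiety:
    """One chemical sub-part of a cofactor with its geometric center."""

    moiety: str
    atom_names: list[str]
    center: np.ndarray
    coords: np.ndarray  # (n_atoms, 3), parallel to atom_names

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if not self.atom_names:
            raise ValueError("moiety must contain at least one atom")


@dataclass(frozen=True)
class BindingAnnotation:
    """External (BioLiP-style) binding-residue annotation for one chain/ligand."""

    pdb_id: str
    chain_id: str
    ligand_code: str
    binding_positions: frozenset

    @staticmethod
    def make(pdb_id, chain_id, ligand_code, positions) -> "BindingAnnotation":
        return BindingAnnotation(pdb_id, chain_id, ligand_code, frozenset(positions))


@dataclass(eq=False)
class BindingTemplate:
    """A moiety-typed group (>=2) of binding residues with their triplets."""

    template_id: str
    source_pdb: str
    source_chain: str
    ligand_code: str
    het_seq: int
    moiety: str
    residues: list[tuple]  # (seq_pos, res_name, Triplet, ss_label)
    ligand_center: np.ndarray

    def __post_init__(self):
        self.ligand_center = np.asarray(self.ligand_center, dtype=float)
        if len(self.residues) < 2:
            raise ValueError(
                f"template {self.template_id} needs >=2 residues, got {len(self.residues)}"
            )
        for seq_pos, res_name, triplet, ss in self.residues:
            if triplet is None:
                raise ValueError(f"template {self.template_id}: residue {seq_pos} has no triplet")

    @property
    def size(self) -> int:
        return len(self.residues)

    def triplets(self) -> list[Triplet]:
        return [t for _, _, t, _ in self.residues]

    def res_names(self) -> list[str]:
        return [r for _, r, _, _ in self.residues]

    def ss_labels(self) -> list[str]:
        return [s for _, _, _, s in self.residues]

    def positions(self) -> list:
        return [p for p, _, _, _ in self.residues]

    def __eq__(self, other):
        if not isinstance(other, BindingTemplate):
            return NotImplemented
        return (
            self.template_id == other.template_id
            and self.source_pdb == other.source_pdb
            and self.source_chain == other.source_chain
            and self.ligand_code == other.ligand_code
            and self.het_seq == other.het_seq
            and self.moiety == other.moiety
            and np.array_equal(self.ligand_center, other.ligand_center)
            and len(self.residues) == len(other.residues)
            and all(
                a[0] == b[0] and a[1] == b[1] and a[2] == b[2] and a[3] == b[3]
                for a, b in zip(self.residues, other.residues)
            )
        )


@dataclass(eq=False)
class TemplateDatabase:
    ligand_kind: str
    templates: list[BindingTemplate] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [t.template_id for t in self.templates]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate template ids in database")

    def __len__(self):
        return len(self.templates)

    def __eq__(self, other):
        if not isinstance(other, TemplateDatabase):
            return NotImplemented
        return (
            self.ligand_kind == other.ligand_kind
            and self.provenance == other.provenance
            and self.templates == other.templates
        )


@dataclass
class TemplateBuildParams:
    """Parameters of template construction."""

    cutoff: float = 3.5  # contact distance, Angstrom
    version_tag: str = "1"


# ---------------------------------------------------------------------------
# Moiety partitioning
# ---------------------------------------------------------------------------

def partition_ligand_moieties(ligand: LigandInstance) -> list[LigandMoiety]:
    """Split a ligand's atoms into its three moieties.

    Assignment is by PDB atom name against the built-in partition tables;
    unrecognized atom names are attached to the nearest moiety center with a
    warning. Centers are unweighted means of member-atom coordinates.
    """
    if ligand.ligand_code not in MOIETY_ATOMS:
        raise MoietyPartitionError(f"unsupported ligand code {ligand.ligand_code!r}")
    tables = MOIETY_ATOMS[ligand.ligand_code]
    order = MOIETY_ORDER[ligand.ligand_code]

    members: dict[str, list[int]] = {m: [] for m in order}
    unknown: list[int] = []
    for idx, atom in enumerate(ligand.atoms):
        for m in order:
            if atom.atom_name in tables[m]:
                members[m].append(idx)
                break
        else:
            unknown.append(idx)
    if all(not v for v in members.values()):
        raise MoietyPartitionError(
            f"no atom name of ligand {ligand.ligand_code} matches the partition tables"
        )

    coords = ligand.atom_coords()
    centers = {m: coords[idx].mean(axis=0) for m, idx in members.items() if idx}
    for idx in unknown:
        warnings.warn(
            f"ligand atom {ligand.atoms[idx].atom_name!r} not in the "
            f"{ligand.ligand_code} partition table; assigned to nearest moiety",
            stacklevel=2,
        )
        nearest = min(centers, key=lambda m: float(np.linalg.norm(coords[idx] - centers[m])))
        members[nearest].append(idx)

    out = []
    for m in order:
        idx = members[m]
        if not idx:
            continue
        out.append(
            LigandMoiety(
                moiety=m,
                atom_names=[ligand.atoms[i].atom_name for i in idx],
                center=coords[idx].mean(axis=0),
                coords=coords[idx],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Binding residue identification
# ---------------------------------------------------------------------------

def _min_distance_to_moiety(residue: ResidueUnit, moiety: LigandMoiety) -> float:
    if not residue.atoms:
        return np.inf
    ra = residue.atom_coords()
    d = np.linalg.norm(ra[:, None, :] - moiety.coords[None, :, :], axis=-1)
    return float(d.min())


def identify_binding_residues(
    chain: list[ResidueUnit],
    moiety: LigandMoiety,
    annotation: BindingAnnotation | None = None,
    cutoff: float = 3.5,
) -> set:
    """Residues of *chain* in contact (any atom within *cutoff*) with *moiety*.

    With an annotation, the geometric contact set is intersected with the
    annotated binding positions.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not chain:
        raise EmptyChainError("chain is empty")
    contacts = {
        r.seq_pos for r in chain if _min_distance_to_moiety(r, moiety) <= cutoff
    }
    if annotation is not None:
        contacts &= set(annotation.binding_positions)
    return contacts


def _moiety_assignment(
    chain: list[ResidueUnit],
    moieties: list[LigandMoiety],
    annotation: BindingAnnotation | None,
    cutoff: float,
) -> dict[str, set]:
    """Per-moiety binding sets for one chain/ligand.

    Without annotation a residue may bind several moieties. With annotation,
    each annotated residue is assigned to its nearest qualifying moiety only.
    """
    if annotation is None:
        return {
            m.moiety: identify_binding_residues(chain, m, None, cutoff)
            for m in moieties
        }
    out: dict[str, set] = {m.moiety: set() for m in moieties}
    for r in chain:
        if r.seq_pos not in annotation.binding_positions:
            continue
        dists = {m.moiety: _min_distance_to_moiety(r, m) for m in moieties}
        qualifying = {m: d for m, d in dists.items() if d <= cutoff}
        if qualifying:
            out[min(qualifying, key=qualifying.get)].add(r.seq_pos)
    return out


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------

def build_templates(
    model: StructureModel,
    annotations: list[BindingAnnotation] | BindingAnnotation | None = None,
    params: TemplateBuildParams | None = None,
) -> TemplateDatabase:
    """Build the binding-residue templates of one structure.

    For each (chain, ligand, moiety) the contact group becomes one
    :class:`BindingTemplate` iff it has at least two residues with triplets.
    """
    params = params or TemplateBuildParams()
    if isinstance(annotations, BindingAnnotation):
        annotations = [annotations]
    if not model.ligands:
        raise MoietyPartitionError(f"model {model.pdb_id} contains no supported ligand")

    kinds = {lig.ligand_code for lig in model.ligands}
    if len(kinds) > 1:
        raise ValueError(f"mixed ligand kinds in one database build: {sorted(kinds)}")
    ligand_kind = kinds.pop()

    templates: list[BindingTemplate] = []
    for lig in model.ligands:
        moieties = partition_ligand_moieties(lig)
        for chain_id, chain in model.chains.items():
            ann = None
            if annotations is not None:
                for a in annotations:
                    if (
                        a.pdb_id.lower() == model.pdb_id.lower()
                        and a.chain_id == chain_id
                        and a.ligand_code == lig.ligand_code
                    ):
                        ann = a
                        break
                if ann is None:
                    continue
            groups = _moiety_assignment(chain, moieties, ann, params.cutoff)
            by_pos = {r.seq_pos: r for r in chain}
            for moiety in moieties:
                positions = sorted(groups[moiety.moiety], key=_pos_key)
                rows = []
                for p in positions:
                    r = by_pos[p]
                    if r.triplet is None:
                        logger.info(
                            "binding residue %s:%s lacks a triplet; dropped from template",
                            chain_id, p,
                        )
                        continue
                    rows.append((p, r.res_name, r.triplet, r.ss_label))
                if len(rows) < 2:
                    if rows or positions:
                        logger.info(
                            "group %s %s/%s %s has <2 usable residues; no template",
                            model.pdb_id, chain_id, lig.het_seq, moiety.moiety,
                        )
                    continue
                tid = f"{model.pdb_id}_{chain_id}_{lig.ligand_code}{lig.het_seq}_{moiety.moiety}"
                templates.append(
                    BindingTemplate(
                        template_id=tid,
                        source_pdb=model.pdb_id,
                        source_chain=chain_id,
                        ligand_code=lig.ligand_code,
                        het_seq=lig.het_seq,
                        moiety=moiety.moiety,
                        residues=rows,
                        ligand_center=moiety.center,
                    )
                )
    if not templates:
        warnings.warn(f"no template could be built from {model.pdb_id}", stacklevel=2)
    return TemplateDatabase(
        ligand_kind=ligand_kind,
        templates=templates,
        provenance={
            "cutoff": params.cutoff,
            "version_tag": params.version_tag,
            "annotation_source": "external" if annotations is not None else "geometric",
        },
    )


def merge_databases(dbs: list[TemplateDatabase]) -> TemplateDatabase:
    """Concatenate template databases of the same ligand kind."""
    dbs = [db for db in dbs if len(db) > 0]
    if not dbs:
        raise ValueError("no non-empty database to merge")
    kinds = {db.ligand_kind for db in dbs}
    if len(kinds) > 1:
        raise ValueError(f"cannot merge databases of mixed ligand kinds {sorted(kinds)}")
    merged = []
    for db in dbs:
        merged.extend(db.templates)
    return TemplateDatabase(
        ligand_kind=kinds.pop(), templates=merged, provenance=dbs[0].provenance
    )


def _pos_key(p):
    return (p, "") if isinstance(p, int) else (int(p[:-1]), p[-1])


# ---------------------------------------------------------------------------
# Serialization (versioned JSON lines)
# ---------------------------------------------------------------------------

def write_template_db(db: TemplateDatabase, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        header = {
            "format": DB_FORMAT,
            "version": DB_VERSION,
            "ligand_kind": db.ligand_kind,
            "provenance": db.provenance,
            "n_templates": len(db.templates),
        }
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for t in db.templates:
            row = {
                "template_id": t.template_id,
                "source_pdb": t.source_pdb,
                "source_chain": t.source_chain,
                "ligand_code": t.ligand_code,
                "het_seq": t.het_seq,
                "moiety": t.moiety,
                "n_residues": len(t.residues),
                "ligand_center": list(t.ligand_center),
                "residues": [
                    {
                        "seq_pos": p,
                        "res_name": rn,
                        "ss": ss,
                        "n": list(tr.n_coord),
                        "ca": list(tr.ca_coord),
                        "c": list(tr.c_coord),
                    }
                    for p, rn, tr, ss in t.residues
                ],
            }
            fh.write(json.dumps(row, sort_keys=True) + "\n")


def read_template_db(path) -> TemplateDatabase:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise TemplateDbFormatError(f"{path}: empty file")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise TemplateDbFormatError(f"{path}: bad header: {exc}") from exc
    if header.get("format") != DB_FORMAT:
        raise TemplateDbFormatError(f"{path}: not a {DB_FORMAT} file")
    if header.get("version") != DB_VERSION:
        raise TemplateDbVersionError(
            f"{path}: version {header.get('version')!r} != supported {DB_VERSION}"
        )
    templates = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            row = json.loads(line)
        except json.JSONDecodeError as exc:
            raise TemplateDbFormatError(f"{path}:{lineno}: bad JSON: {exc}") from exc
        tid = row.get("template_id", f"<line {lineno}>")
        residues = row.get("residues", [])
        if row.get("n_residues") != len(residues):
            raise TemplateDbFormatError(
                f"{path}: template {tid}: residue count mismatch "
                f"({row.get('n_residues')} declared, {len(residues)} present)"
            )
        try:
            rows = [
                (
                    r["seq_pos"],
                    r["res_name"],
                    Triplet(np.array(r["n"]), np.array(r["ca"]), np.array(r["c"])),
                    r["ss"],
                )
                for r in residues
            ]
            templates.append(
                BindingTemplate(
                    template_id=row["template_id"],
                    source_pdb=row["source_pdb"],
                    source_chain=row["source_chain"],
                    ligand_code=row["ligand_code"],
                    het_seq=row["het_seq"],
                    moiety=row["moiety"],
                    residues=rows,
                    ligand_center=np.array(row["ligand_center"], dtype=float),
                )
            )
        except (KeyError, ValueError) as exc:
            raise TemplateDbFormatError(f"{path}: template {tid}: {exc}") from exc
    return TemplateDatabase(
        ligand_kind=header["ligand_kind"],
        templates=templates,
        provenance=header.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# BioLiP-style annotations
# ---------------------------------------------------------------------------

def read_biolip_annotations(text: str) -> list[BindingAnnotation]:
    """Parse whitespace-delimited rows: pdb chain ligand pos [pos ...].

    Residue tokens like ``G37`` parse to position 37; tokens with an
    insertion code (``G37A``) keep it as a string key. Unparseable tokens
    skip the row with a warning; duplicate rows are deduplicated.
    """
    out: list[BindingAnnotation] = []
    seen = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            warnings.warn(f"annotation line {lineno}: too few fields; skipped", stacklevel=2)
            continue
        pdb_id, chain_id, ligand_code = fields[0], fields[1], fields[2]
        positions = []
        ok = True
        for token in fields[3:]:
            pos = _parse_residue_token(token)
            if pos is None:
                warnings.warn(
                    f"annotation line {lineno}: bad residue token {token!r}; row skipped",
                    stacklevel=2,
                )
                ok = False
                break
            positions.append(pos)
        if not ok:
            continue
        if not positions:
            warnings.warn(f"annotation line {lineno}: empty position list", stacklevel=2)
        ann = BindingAnnotation.make(pdb_id, chain_id, ligand_code, positions)
        key = (ann.pdb_id, ann.chain_id, ann.ligand_code, ann.binding_positions)
        if key in seen:
            continue
        seen.add(key)
        out.append(ann)
    return out


def _parse_residue_token(token: str):
    """'G37' -> 37, 'G37A' -> '37A', '41' -> 41; None if unparseable."""
    body = token
    if body and body[0].isalpha():
        body = body[1:]
    if not body:
        return None
    if body.isdigit() or (body[0] == "-" and body[1:].isdigit()):
        return int(body)
    if body[:-1].isdigit() and body[-1].isalpha():
        return body
    return None


def format_annotations(annotations: list[BindingAnnotation]) -> str:
    """Inverse of :func:`read_biolip_annotations` (one-letter code omitted)."""
    lines = []
    for a in annotations:
        toks = " ".join(str(p) for p in sorted(a.binding_positions, key=_pos_key))
        lines.append(f"{a.pdb_id} {a.chain_id} {a.ligand_code} {toks}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Composition statistics
# ---------------------------------------------------------------------------

def binding_composition_stats(db: TemplateDatabase, models: list[StructureModel]):
    """Residue-type and atom-type composition of binding sites.

    Returns ``(freq_df, atom_df)``: per (moiety, residue type) the binding
    frequency, whole-protein frequency and their ratio; and contact counts of
    protein atoms within 3.5 A of moiety atoms split backbone/side-chain.
    """
    import pandas as pd

    if len(db) == 0:
        raise ValueError("empty template database")

    whole_counts: dict[str, int] = {}
    total_whole = 0
    for model in models:
        for chain in model.chains.values():
            for r in chain:
                whole_counts[r.res_name] = whole_counts.get(r.res_name, 0) + 1
                total_whole += 1

    bind_counts: dict[str, dict[str, int]] = {}
    for t in db.templates:
        d = bind_counts.setdefault(t.moiety, {})
        for rn in t.res_names():
            d[rn] = d.get(rn, 0) + 1

    rows = []
    for moiety, counts in sorted(bind_counts.items()):
        total_bind = sum(counts.values())
        for rn, c in sorted(counts.items()):
            bind_freq = c / total_bind
            whole_freq = whole_counts.get(rn, 0) / total_whole if total_whole else 0.0
            rows.append(
                {
                    "moiety": moiety,
                    "res_name": rn,
                    "binding_freq": bind_freq,
                    "whole_freq": whole_freq,
                    "ratio": bind_freq / whole_freq if whole_freq > 0 else np.inf,
                }
            )
    freq_df = pd.DataFrame(rows)

    contact_rows: dict[tuple, int] = {}
    for model in models:
        for lig in model.ligands:
            moieties = partition_ligand_moieties(lig)
            for chain in model.chains.values():
                for r in chain:
                    if not r.atoms:
                        continue
                    ra = r.atom_coords()
                    for m in moieties:
                        d = np.linalg.norm(
                            ra[:, None, :] - m.coords[None, :, :], axis=-1
                        ).min(axis=1)
                        for atom, dist in zip(r.atoms, d):
                            if dist > 3.5:
                                continue
                            part = (
                                "backbone"
                                if atom.atom_name in BACKBONE_ATOMS
                                else "side_chain"
                            )
                            elem = atom.element or atom.atom_name[0]
                            key = (m.moiety, part, elem)
                            contact_rows[key] = contact_rows.get(key, 0) + 1
    atom_df = pd.DataFrame(
        [
            {"moiety": m, "part": p, "element": e, "count": c}
            for (m, p, e), c in sorted(contact_rows.items())
        ]
    )
    return freq_df, atom_df
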