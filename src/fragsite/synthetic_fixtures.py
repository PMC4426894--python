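"""Download-free synthetic test inputs.

Ideal N-Ca-C backbones built from internal coordinates, binding sites
planted into chains under a random rigid motion with controllable Gaussian
noise, pseudo-ligands whose atom names exercise the real moiety-partition
code path, and complete toy datasets for end-to-end evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from ._geometry import place_atom, unit
from .structure_io import (
    AtomRecord,
    ONE_TO_THREE,
    ResidueUnit,
    StructureModel,
    Triplet,
    LigandInstance,
)
from .template_db import (
    BindingAnnotation,
    BindingTemplate,
    MOIETY_ATOMS,
    MOIETY_ORDER,
    TemplateBuildParams,
    TemplateDatabase,
    build_templates,
    merge_databases,
)

# Ideal backbone geometry (bond lengths in Angstrom, angles in degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.9
OMEGA = 180.0

PHI_PSI = {"H": (-57.0, -47.0), "E": (-119.0, 113.0)}

_AA1 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureSpec:
    """Specification of one synthetic chain."""

    n_residues: int
    ss_pattern: str
    sequence: str
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.ss_pattern) != self.n_residues or len(self.sequence) != self.n_residues:
            raise ValueError("ss_pattern and sequence must have length n_residues")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        bad = set(self.ss_pattern) - {"H", "E", "-"}
        if bad:
            raise ValueError(f"invalid ss symbols {sorted(bad)}")


@dataclass
class PlantedSite:
    """Ground truth of one planted binding site."""

    template: BindingTemplate
    target_positions: list
    true_center_by_moiety: dict[str, np.ndarray]


def generate_ideal_backbone(spec: FixtureSpec, chain_id: str = "A") -> list[ResidueUnit]:
    """Chain of N-Ca-C residues with ideal bonds/angles and per-state phi/psi.

    Coil ('-') residues draw phi/psi from broad windows using the seeded RNG,
    so generation is a pure function of the spec.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    phis = np.empty(n)
    psis = np.empty(n)
    for i, s in enumerate(spec.ss_pattern):
        if s in PHI_PSI:
            phis[i], psis[i] = PHI_PSI[s]
        else:
            phis[i] = rng.uniform(-160.0, -50.0)
            psis[i] = rng.uniform(-60.0, 170.0)

    coords = np.empty((n, 3, 3))  # residue x (N, CA, C) x xyz
    coords[0, 0] = (0.0, 0.0, 0.0)
    coords[0, 1] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        pn, pca, pc = coords[i - 1]
        ni = place_atom(pn, pca, pc, BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        cai = place_atom(pca, pc, ni, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        ci = place_atom(pc, ni, cai, BOND_CA_C, ANGLE_N_CA_C, phis[i])
        coords[i] = (ni, cai, ci)

    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)

    chain = []
    for i in range(n):
        res_name = ONE_TO_THREE[spec.sequence[i]]
        atoms = [
            AtomRecord("N", "N", coords[i, 0]),
            AtomRecord("CA", "C", coords[i, 1]),
            AtomRecord("C", "C", coords[i, 2]),
        ]
        chain.append(
            ResidueUnit(
                chain_id=chain_id,
                seq_pos=i + 1,
                res_name=res_name,
                triplet=Triplet(*coords[i]),
                ss_label=spec.ss_pattern[i],
                atoms=atoms,
            )
        )
    return chain


def random_ss_pattern(n: int, rng) -> str:
    """Segments of helix (6-12), strand (4-8) and coil (3-6)."""
    out = []
    while len(out) < n:
        kind = rng.choice(["H", "E", "-"])
        length = {
            "H": rng.integers(6, 13),
            "E": rng.integers(4, 9),
            "-": rng.integers(3, 7),
        }[kind]
        out.extend([kind] * int(length))
    return "".join(out[:n])


def random_sequence(n: int, rng) -> str:
    return "".join(rng.choice(list(_AA1), size=n))


def _ideal_triplet_at(ca: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """(3, 3) N/CA/C coordinates of an ideally bonded residue at *ca*."""
    ang = np.radians(ANGLE_N_CA_C)
    local = np.array(
        [
            [BOND_N_CA, 0.0, 0.0],
            [0.0, 0.0, 0.0],
            [BOND_CA_C * np.cos(ang), BOND_CA_C * np.sin(ang), 0.0],
        ]
    )
    return local @ rotation.T + ca


def plant_binding_site(
    chain: list[ResidueUnit],
    template: BindingTemplate,
    noise_sigma: float,
    seed: int,
    positions: list[int] | None = None,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> tuple[list[ResidueUnit], PlantedSite]:
    """Write a template's residues into a chain under a rigid motion + noise.

    Template triplets, residue names and SS labels overwrite a seeded random
    subset of chain positions (or the given ``positions``, as 0-based chain
    indices). The rigid motion defaults to a random rotation plus a
    translation placing the site outside the chain's bounding sphere; the
    template's ligand center is transported noise-free and recorded as truth.
    """
    size = template.size
    if len(chain) < size + 4:
        raise ValueError("chain too short for template")
    rng = np.random.default_rng(seed)
    if positions is None:
        positions = sorted(rng.choice(len(chain), size=size, replace=False))
    if len(positions) != size:
        raise ValueError("positions must match template size")

    if rotation is None:
        rotation = Rotation.random(rng=rng).as_matrix()
    if translation is None:
        ca = np.stack([r.triplet.ca_coord for r in chain if r.triplet is not None])
        centroid = ca.mean(axis=0)
        radius = float(np.linalg.norm(ca - centroid, axis=1).max())
        direction = unit(rng.normal(size=3))
        target = centroid + direction * (radius + 25.0)
        src_centroid = np.stack([t.ca_coord for t in template.triplets()]).mean(axis=0)
        translation = target - rotation @ src_centroid

    new_chain = list(chain)
    target_positions = []
    for idx, (seq_pos, res_name, triplet, ss) in zip(positions, template.residues):
        coords = triplet.coords @ rotation.T + translation
        if noise_sigma > 0:
            coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
        old = chain[idx]
        atoms = [
            AtomRecord("N", "N", coords[0]),
            AtomRecord("CA", "C", coords[1]),
            AtomRecord("C", "C", coords[2]),
        ]
        new_chain[idx] = ResidueUnit(
            chain_id=old.chain_id,
            seq_pos=old.seq_pos,
            res_name=res_name,
            triplet=Triplet(*coords),
            ss_label=ss,
            atoms=atoms,
        )
        target_positions.append(old.seq_pos)
    true_center = rotation @ template.ligand_center + translation
    site = PlantedSite(
        template=template,
        target_positions=target_positions,
        true_center_by_moiety={template.moiety: true_center},
    )
    return new_chain, site


# ---------------------------------------------------------------------------
# Toy dataset generation
# ---------------------------------------------------------------------------

@dataclass
class ToyParams:
    min_len: int = 60
    max_len: int = 120
    min_template_size: int = 2
    max_template_size: int = 6
    noise_lo: float = 0.1
    noise_hi: float = 0.5
    center_side_lo: float = 6.0
    center_side_hi: float = 7.5
    residue_radius: float = 2.5  # Ca distance from moiety center
    ligand_atom_radius: float = 0.8
    cutoff: float = 3.5


@dataclass
class ArchetypeSite:
    """The shared noise-free binding site copied into every toy protein."""

    moieties: list[str]
    centers: dict[str, np.ndarray]
    triplets: dict[str, list[np.ndarray]]  # (3,3) coordinate blocks
    res_names: dict[str, list[str]]
    ss_labels: dict[str, list[str]]
    ligand_atoms: dict[str, list[tuple[str, np.ndarray]]]


@dataclass
class ToyProtein:
    model: StructureModel
    annotations: list[BindingAnnotation]
    true_centers: dict[str, np.ndarray]
    planted_positions: dict[str, list]
    noise_sigma: float


@dataclass
class ToyDataset:
    proteins: list[ToyProtein]
    db: TemplateDatabase

    def as_eval_dataset(self):
        return [(p.model, p.annotations) for p in self.proteins]


_TETRA = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


def _build_archetype(rng, ligand_kind: str, params: ToyParams) -> ArchetypeSite:
    moieties = list(MOIETY_ORDER[ligand_kind])
    # moiety centers: a triangle with sides in the configured range
    s12 = rng.uniform(params.center_side_lo, params.center_side_hi)
    s13 = rng.uniform(params.center_side_lo, params.center_side_hi)
    s23 = rng.uniform(params.center_side_lo, params.center_side_hi)
    x3 = (s12**2 + s13**2 - s23**2) / (2 * s12)
    y3 = np.sqrt(max(s13**2 - x3**2, 0.25))
    raw_centers = [np.zeros(3), np.array([s12, 0.0, 0.0]), np.array([x3, y3, 0.0])]
    centers = dict(zip(moieties, raw_centers))
    g = np.mean(raw_centers, axis=0)

    ligand_atoms: dict[str, list[tuple[str, np.ndarray]]] = {}
    for m in moieties:
        names = MOIETY_ATOMS[ligand_kind][m][:4]
        ligand_atoms[m] = [
            (name, centers[m] + params.ligand_atom_radius * v)
            for name, v in zip(names, _TETRA)
        ]

    triplets: dict[str, list[np.ndarray]] = {}
    res_names: dict[str, list[str]] = {}
    ss_labels: dict[str, list[str]] = {}
    for m in moieties:
        size = int(rng.integers(params.min_template_size, params.max_template_size + 1))
        triplets[m], res_names[m], ss_labels[m] = [], [], []
        others = [
            np.asarray(xyz)
            for mm in moieties
            if mm != m
            for _, xyz in ligand_atoms[mm]
        ]
        outward = unit(centers[m] - g)
        for _ in range(size):
            # spread residues around the center (long baselines give
            # well-conditioned cluster transforms) while keeping them
            # clear of the other moieties' atoms
            for _attempt in range(80):
                direction = unit(0.35 * outward + rng.normal(size=3))
                ca = centers[m] + params.residue_radius * direction
                coords = _ideal_triplet_at(ca, Rotation.random(rng=rng).as_matrix())
                d_other = min(
                    float(np.linalg.norm(coords[:, None, :] - np.stack(others)[None], axis=-1).min()),
                    np.inf,
                )
                own = np.stack([xyz for _, xyz in ligand_atoms[m]])
                d_own = float(
                    np.linalg.norm(coords[:, None, :] - own[None], axis=-1).min()
                )
                if d_own <= params.cutoff - 0.2 and d_other >= params.cutoff + 0.7:
                    break
            triplets[m].append(coords)
            res_names[m].append(ONE_TO_THREE[rng.choice(list(_AA1))])
            ss_labels[m].append(str(rng.choice(["H", "E", "-"])))
    return ArchetypeSite(
        moieties=moieties,
        centers=centers,
        triplets=triplets,
        res_names=res_names,
        ss_labels=ss_labels,
        ligand_atoms=ligand_atoms,
    )


def make_toy_dataset(
    n_proteins: int,
    params: ToyParams | None = None,
    seed: int = 0,
    ligand_kind: str = "NAD",
) -> ToyDataset:
    """Generate a benchmark of proteins sharing one planted 3-moiety site.

    Every protein receives a noisy rigid-motion copy of the same archetype
    site plus a pseudo-ligand whose HETATM names exercise the real moiety
    partition, so templates can be rebuilt from scratch with
    :func:`fragsite.template_db.build_templates`. Ground-truth binding
    labels and moiety centers are attached.
    """
    if n_proteins < 2:
        raise ValueError("need at least 2 proteins")
    params = params or ToyParams()
    rng = np.random.default_rng(seed)
    archetype = _build_archetype(rng, ligand_kind, params)

    proteins: list[ToyProtein] = []
    dbs: list[TemplateDatabase] = []
    for p in range(n_proteins):
        pdb_id = f"syn{p:03d}"
        n_res = int(rng.integers(params.min_len, params.max_len + 1))
        spec = FixtureSpec(
            n_residues=n_res,
            ss_pattern=random_ss_pattern(n_res, rng),
            sequence=random_sequence(n_res, rng),
            noise_sigma=0.0,
            seed=int(rng.integers(0, 2**31)),
        )
        chain = generate_ideal_backbone(spec)
        noise_sigma = float(rng.uniform(params.noise_lo, params.noise_hi))

        sizes = {m: len(archetype.triplets[m]) for m in archetype.moieties}
        total = sum(sizes.values())
        picked = sorted(rng.choice(n_res, size=total, replace=False))
        rng.shuffle(picked)
        cursor = 0

        # one rigid motion for the whole site, placed outside the chain
        rotation = Rotation.random(rng=rng).as_matrix()
        ca = np.stack([r.triplet.ca_coord for r in chain])
        centroid = ca.mean(axis=0)
        radius = float(np.linalg.norm(ca - centroid, axis=1).max())
        direction = unit(rng.normal(size=3))
        site_centroid = np.mean(
            [c for m in archetype.moieties for c in (archetype.centers[m],)], axis=0
        )
        translation = (
            centroid + direction * (radius + 25.0) - rotation @ site_centroid
        )

        planted_positions: dict[str, list] = {}
        true_centers: dict[str, np.ndarray] = {}
        for m in archetype.moieties:
            idxs = sorted(picked[cursor : cursor + sizes[m]])
            cursor += sizes[m]
            planted_positions[m] = [chain[i].seq_pos for i in idxs]
            true_centers[m] = rotation @ archetype.centers[m] + translation
            for i, block, rn, ss in zip(
                idxs, archetype.triplets[m], archetype.res_names[m], archetype.ss_labels[m]
            ):
                coords = block @ rotation.T + translation
                if noise_sigma > 0:
                    coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
                chain[i] = ResidueUnit(
                    chain_id="A",
                    seq_pos=chain[i].seq_pos,
                    res_name=rn,
                    triplet=Triplet(*coords),
                    ss_label=ss,
                    atoms=[
                        AtomRecord("N", "N", coords[0]),
                        AtomRecord("CA", "C", coords[1]),
                        AtomRecord("C", "C", coords[2]),
                    ],
                )

        lig_atoms = [
            AtomRecord(name, name[0], rotation @ xyz + translation)
            for m in archetype.moieties
            for name, xyz in archetype.ligand_atoms[m]
        ]
        ligand = LigandInstance(
            ligand_code=ligand_kind, chain_id="A", het_seq=901, atoms=lig_atoms
        )
        model = StructureModel(pdb_id=pdb_id, chains={"A": chain}, ligands=[ligand])
        db_p = build_templates(
            model, None, TemplateBuildParams(cutoff=params.cutoff)
        )
        dbs.append(db_p)
        binding_positions = sorted(
            {pos for t in db_p.templates for pos in t.positions()}
        )
        annotations = [
            BindingAnnotation.make(pdb_id, "A", ligand_kind, binding_positions)
        ]
        proteins.append(
            ToyProtein(
                model=model,
                annotations=annotations,
                true_centers=true_centers,
                planted_positions=planted_positions,
                noise_sigma=noise_sigma,
            )
        )
    return ToyDataset(proteins=proteins, db=merge_databases(dbs))
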