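import numpy as np
import pytest

from fragsite.errors import (
    MoietyPartitionError,
    TemplateDbFormatError,
    TemplateDbVersionError,
)
from fragsite.structure_io import (
    AtomRecord,
    LigandInstance,
    ResidueUnit,
    StructureModel,
    Triplet,
)
from fragsite.template_db import (
    BindingAnnotation,
    BindingTemplate,
    MOIETY_ATOMS,
    MOIETY_ORDER,
    TemplateDatabase,
    binding_composition_stats,
    build_templates,
    identify_binding_residues,
    partition_ligand_moieties,
    read_biolip_annotations,
    read_template_db,
    write_template_db,
)


def _atom(name, xyz, element=None):
    return AtomRecord(name, element or name[0], np.asarray(xyz, dtype=float))


def _triplet_at(ca):
    ca = np.asarray(ca, dtype=float)
    return Triplet(ca + [1.458, 0, 0], ca, ca + [-0.546, 1.424, 0])


def _residue(seq_pos, ca, res_name="GLY", chain_id="A"):
    t = _triplet_at(ca)
    return ResidueUnit(
        chain_id=chain_id,
        seq_pos=seq_pos,
        res_name=res_name,
        triplet=t,
        ss_label="-",
        atoms=[
            _atom("N", t.n_coord),
            _atom("CA", t.ca_coord, "C"),
            _atom("C", t.c_coord),
        ],
    )


class TestMoietyPartitionTables:
    @pytest.mark.parametrize("ligand,expected_total", [("NAD", 44), ("FAD", 53)])
    def test_partition_covers_ccd_heavy_atoms(self, ligand, expected_total):
        tables = MOIETY_ATOMS[ligand]
        names = [n for group in tables.values() for n in group]
        assert len(names) == expected_total
        assert len(set(names)) == expected_total  # disjoint

    def test_moiety_order(self):
        assert MOIETY_ORDER["NAD"] == ("nicotinamide", "adenosine", "phosphate")
        assert MOIETY_ORDER["FAD"] == ("flavin", "adenosine", "phosphate")


class TestPartitionLigandMoieties:
    def _full_nad(self):
        atoms = []
        for group in MOIETY_ATOMS["NAD"].values():
            for name in group:
                atoms.append(_atom(name, np.random.default_rng(0).uniform(0, 5, 3)))
        return LigandInstance("NAD", "A", 500, atoms)

    def test_full_nad_partition(self):
        moieties = partition_ligand_moieties(self._full_nad())
        by_name = {m.moiety: m for m in moieties}
        assert set(by_name["phosphate"].atom_names) == set(
            MOIETY_ATOMS["NAD"]["phosphate"]
        )
        total = sum(len(m.atom_names) for m in moieties)
        assert total == 44

    def test_three_atom_synthetic_centers(self):
        atoms = [
            _atom("PA", [1, 2, 3]),
            _atom("C1B", [4, 5, 6]),
            _atom("C1D", [7, 8, 9]),
        ]
        moieties = partition_ligand_moieties(LigandInstance("NAD", "A", 1, atoms))
        centers = {m.moiety: m.center for m in moieties}
        np.testing.assert_allclose(centers["phosphate"], [1, 2, 3])
        np.testing.assert_allclose(centers["adenosine"], [4, 5, 6])
        np.testing.assert_allclose(centers["nicotinamide"], [7, 8, 9])

    def test_phosphate_center_is_mean(self):
        atoms = [
            _atom("PA", [0, 0, 0]),
            _atom("PN", [2, 0, 0]),
            _atom("O3", [1, 0, 0]),
            _atom("C1B", [9, 9, 9]),
            _atom("C1D", [-9, -9, -9]),
        ]
        moieties = partition_ligand_moieties(LigandInstance("NAD", "A", 1, atoms))
        phos = next(m for m in moieties if m.moiety == "phosphate")
        np.testing.assert_allclose(phos.center, [1, 0, 0])

    def test_unknown_atom_assigned_nearest_with_warning(self):
        atoms = [
            _atom("PA", [0, 0, 0]),
            _atom("C1B", [10, 0, 0]),
            _atom("C1D", [20, 0, 0]),
            _atom("XX9", [0.5, 0, 0], "X"),
        ]
        with pytest.warns(UserWarning, match="not in the NAD partition"):
            moieties = partition_ligand_moieties(LigandInstance("NAD", "A", 1, atoms))
        phos = next(m for m in moieties if m.moiety == "phosphate")
        assert "XX9" in phos.atom_names

    def test_all_unrecognized_raises(self):
        atoms = [_atom("QQ1", [0, 0, 0], "Q"), _atom("QQ2", [1, 0, 0], "Q")]
        with pytest.raises(MoietyPartitionError):
            partition_ligand_moieties(LigandInstance("NAD", "A", 1, atoms))


def _moiety_at(center, moiety="phosphate"):
    from fragsite.template_db import LigandMoiety

    center = np.asarray(center, dtype=float)
    return LigandMoiety(
        moiety=moiety, atom_names=["PA"], center=center, coords=center[None, :]
    )


class TestIdentifyBindingResidues:
    def test_within_cutoff(self):
        chain = [_residue(1, [3.4, 0, 0])]
        # CA at 3.4 A from the single moiety atom at origin
        out = identify_binding_residues(chain, _moiety_at([0, 0, 0]), cutoff=3.5)
        assert out == {1}

    def test_just_outside_cutoff(self):
        chain = [_residue(1, [0, 0, 5.2])]
        # nearest atom is CA at 5.2; N/C are further from origin in x/y
        out = identify_binding_residues(chain, _moiety_at([0, 0, 0]), cutoff=3.5)
        assert out == set()

    def test_planted_vs_decoys_matches_brute_force(self, rng):
        center = np.array([50.0, 0.0, 0.0])
        chain = []
        planted = []
        for i in range(4):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            chain.append(_residue(i + 1, center + 2.0 * direction))
            planted.append(i + 1)
        for i in range(16):
            chain.append(_residue(100 + i, rng.uniform(-20, 20, 3)))
        moiety = _moiety_at(center, "nicotinamide")
        out = identify_binding_residues(chain, moiety, cutoff=3.5)
        # independent brute-force all-pairs scan
        expected = set()
        for r in chain:
            for a in r.atoms:
                if np.linalg.norm(a.coords - center) <= 3.5:
                    expected.add(r.seq_pos)
                    break
        assert out == expected
        assert set(planted) <= out

    def test_annotation_intersects(self):
        chain = [_residue(1, [2, 0, 0]), _residue(2, [2.5, 0, 0])]
        ann = BindingAnnotation.make("x", "A", "NAD", [2])
        out = identify_binding_residues(
            chain, _moiety_at([0, 0, 0]), annotation=ann, cutoff=3.5
        )
        assert out == {2}

    def test_empty_chain_raises(self):
        from fragsite.errors import EmptyChainError

        with pytest.raises(EmptyChainError):
            identify_binding_residues([], _moiety_at([0, 0, 0]))


def _site_model(counts=(4, 3, 5)):
    """Protein with planted binder groups near three pseudo-moiety centers."""
    rng = np.random.default_rng(5)
    centers = {
        "nicotinamide": np.array([60.0, 0.0, 0.0]),
        "adenosine": np.array([60.0, 8.0, 0.0]),
        "phosphate": np.array([68.0, 4.0, 0.0]),
    }
    lig_names = {"nicotinamide": "C1D", "adenosine": "C1B", "phosphate": "PA"}
    chain = []
    pos = 1
    expected = {}
    for (moiety, center), k in zip(centers.items(), counts):
        expected[moiety] = []
        for _ in range(k):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            chain.append(_residue(pos, center + 2.0 * d))
            expected[moiety].append(pos)
            pos += 1
    for _ in range(10):
        chain.append(_residue(pos, rng.uniform(-30, 0, 3)))
        pos += 1
    ligand = LigandInstance(
        "NAD", "A", 900, [_atom(lig_names[m], c) for m, c in centers.items()]
    )
    model = StructureModel("test", chains={"A": chain}, ligands=[ligand])
    return model, expected


class TestBuildTemplates:
    def test_counts_per_moiety(self):
        model, expected = _site_model((4, 3, 5))
        db = build_templates(model)
        sizes = {t.moiety: t.size for t in db.templates}
        assert sizes == {"nicotinamide": 4, "adenosine": 3, "phosphate": 5}
        for t in db.templates:
            assert t.positions() == expected[t.moiety]

    def test_single_residue_group_dropped(self):
        model, _ = _site_model((1, 2, 2))
        db = build_templates(model)
        assert {t.moiety for t in db.templates} == {"adenosine", "phosphate"}

    def test_two_residue_group_kept(self):
        model, _ = _site_model((2, 2, 2))
        db = build_templates(model)
        assert all(t.size == 2 for t in db.templates)

    def test_no_ligand_raises(self):
        model, _ = _site_model()
        model.ligands = []
        with pytest.raises(MoietyPartitionError):
            build_templates(model)

    def test_never_emits_undersized_or_tripletless(self, toy_small):
        for t in toy_small.db.templates:
            assert t.size >= 2
            assert all(tr is not None for tr in t.triplets())

    def test_template_requires_two_residues(self):
        with pytest.raises(ValueError):
            BindingTemplate(
                template_id="x",
                source_pdb="p",
                source_chain="A",
                ligand_code="NAD",
                het_seq=1,
                moiety="phosphate",
                residues=[(1, "GLY", _triplet_at([0, 0, 0]), "-")],
                ligand_center=np.zeros(3),
            )


class TestTemplateDbRoundTrip:
    def test_round_trip_identity(self, toy_small, tmp_path):
        path = tmp_path / "db.jsonl"
        write_template_db(toy_small.db, path)
        db2 = read_template_db(path)
        assert db2 == toy_small.db

    def test_center_precision(self, toy_small, tmp_path):
        path = tmp_path / "db.jsonl"
        write_template_db(toy_small.db, path)
        db2 = read_template_db(path)
        for t1, t2 in zip(toy_small.db.templates, db2.templates):
            assert np.max(np.abs(t1.ligand_center - t2.ligand_center)) <= 1e-9

    def test_corrupted_count_raises_with_template_name(self, toy_small, tmp_path):
        path = tmp_path / "db.jsonl"
        write_template_db(toy_small.db, path)
        lines = path.read_text().splitlines()
        import json

        row = json.loads(lines[1])
        row["n_residues"] += 1
        lines[1] = json.dumps(row)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TemplateDbFormatError, match=row["template_id"]):
            read_template_db(path)

    def test_version_mismatch_raises(self, toy_small, tmp_path):
        path = tmp_path / "db.jsonl"
        write_template_db(toy_small.db, path)
        lines = path.read_text().splitlines()
        import json

        header = json.loads(lines[0])
        header["version"] = 99
        lines[0] = json.dumps(header)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TemplateDbVersionError):
            read_template_db(path)


class TestReadBiolipAnnotations:
    def test_basic_row(self):
        anns = read_biolip_annotations("1dxy A NAD G12 R15 D37\n")
        assert len(anns) == 1
        assert anns[0].binding_positions == frozenset({12, 15, 37})
        assert anns[0].ligand_code == "NAD"

    def test_empty_position_list_warns(self):
        with pytest.warns(UserWarning, match="empty position list"):
            anns = read_biolip_annotations("1dxy A NAD\n")
        assert anns[0].binding_positions == frozenset()

    def test_duplicates_removed(self):
        text = "1dxy A NAD G12\n1dxy A NAD G12\n"
        assert len(read_biolip_annotations(text)) == 1

    def test_bad_token_skips_row(self):
        with pytest.warns(UserWarning, match="bad residue token"):
            anns = read_biolip_annotations("1dxy A NAD G12 ??\n2abc B FAD K7 K9\n")
        assert len(anns) == 1
        assert anns[0].pdb_id == "2abc"

    def test_insertion_code_token(self):
        anns = read_biolip_annotations("1dxy A NAD G37A\n")
        assert anns[0].binding_positions == frozenset({"37A"})


class TestBindingCompositionStats:
    def test_all_glycine_trivial(self):
        chain = [_residue(i + 1, [i * 4.0, 50, 50]) for i in range(10)]
        t = BindingTemplate(
            template_id="t1",
            source_pdb="p",
            source_chain="A",
            ligand_code="NAD",
            het_seq=1,
            moiety="phosphate",
            residues=[
                (1, "GLY", chain[0].triplet, "-"),
                (2, "GLY", chain[1].triplet, "-"),
            ],
            ligand_center=np.zeros(3),
        )
        db = TemplateDatabase("NAD", [t])
        model = StructureModel("p", chains={"A": chain})
        freq, _ = binding_composition_stats(db, [model])
        row = freq[(freq.moiety == "phosphate") & (freq.res_name == "GLY")].iloc[0]
        assert row.binding_freq == 1.0
        assert row.whole_freq == 1.0
        assert row.ratio == 1.0

    def test_serine_ratio(self):
        # 3 serine binders among 5 binders; whole-protein serine freq 0.10
        chain = []
        for i in range(40):
            name = "SER" if i < 4 else "GLY"
            chain.append(_residue(i + 1, [i * 4.0, 50, 50], res_name=name))
        residues = [
            (i + 1, "SER" if i < 3 else "GLY", chain[i].triplet, "-")
            for i in range(5)
        ]
        t = BindingTemplate(
            template_id="t1", source_pdb="p", source_chain="A",
            ligand_code="NAD", het_seq=1, moiety="adenosine",
            residues=residues, ligand_center=np.zeros(3),
        )
        db = TemplateDatabase("NAD", [t])
        model = StructureModel("p", chains={"A": chain})
        freq, _ = binding_composition_stats(db, [model])
        row = freq[(freq.moiety == "adenosine") & (freq.res_name == "SER")].iloc[0]
        assert row.binding_freq == pytest.approx(0.6)
        assert row.whole_freq == pytest.approx(0.1)
        assert row.ratio == pytest.approx(6.0)

    def test_frequencies_sum_to_one(self, toy_small):
        freq, _ = binding_composition_stats(
            toy_small.db, [p.model for p in toy_small.proteins]
        )
        for _, sub in freq.groupby("moiety"):
            assert sub.binding_freq.sum() == pytest.approx(1.0)

    def test_atom_contact_classification(self):
        # backbone N at 3.4 A from a flavin atom, side-chain OG at 3.6 A
        res = _residue(1, [100, 100, 100])
        res.atoms = [
            _atom("N", [3.4, 0, 0]),
            _atom("OG", [3.6, 0, 0], "O"),
        ]
        chain = [res, _residue(2, [0, 50, 0]), _residue(3, [0, 54, 0])]
        lig = LigandInstance("FAD", "A", 1, [_atom("N5", [0, 0, 0])])
        model = StructureModel("p", chains={"A": chain}, ligands=[lig])
        t = BindingTemplate(
            template_id="t1", source_pdb="p", source_chain="A",
            ligand_code="FAD", het_seq=1, moiety="flavin",
            residues=[
                (2, "GLY", chain[1].triplet, "-"),
                (3, "GLY", chain[2].triplet, "-"),
            ],
            ligand_center=np.zeros(3),
        )
        db = TemplateDatabase("FAD", [t])
        _, atom_df = binding_composition_stats(db, [model])
        backbone_n = atom_df[
            (atom_df.part == "backbone") & (atom_df.element == "N")
        ]
        assert backbone_n["count"].sum() == 1
        side_o = atom_df[(atom_df.part == "side_chain") & (atom_df.element == "O")]
        assert side_o.empty

    def test_empty_db_raises(self):
        with pytest.raises(ValueError):
            binding_composition_stats(TemplateDatabase("NAD", []), [])
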