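"""Structure I/O, atom selection, domain enumeration, generator invariants."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from lwph.structures_io import (
    EmptyStructureError,
    PairingError,
    PDBFormatError,
    Structure,
    build_base_pair,
    build_base_step,
    build_duplex,
    domains_to_json,
    enumerate_local_domains,
    read_pdb,
    select_atoms,
    write_pdb,
)

MINIMAL_PDB = """\
ATOM      1  N1   DA A   1      11.000  12.000  13.000  1.00  0.00           N
ATOM      2  C2   DT B   2      12.000  12.000  13.000  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N1   DA A   1      11.000  12.000  13.000  1.00  0.00           N
ENDMDL
MODEL        2
ATOM      1  N1   DA A   1      11.000  12.000  14.000  1.00  0.00           N
ENDMDL
END
"""

ALTLOC_PDB = """\
ATOM      1  N1 A DA A   1      11.000  12.000  13.000  0.50  0.00           N
ATOM      2  N1 B DA A   1      99.000  99.000  99.000  0.50  0.00           N
ATOM      3  C2   DA A   1      12.000  12.000  13.000  1.00  0.00           C
END
"""


class TestReadPDB:
    def test_minimal_two_atoms(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        s = read_pdb(p)
        assert s.n_atoms == 2
        assert len(s.residues()) == 2
        assert s.atoms[0].restype == "A"

    def test_two_models_share_roster(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(TWO_MODEL_PDB)
        s = read_pdb(p)
        assert s.n_models == 2
        assert s.models[1][0][2] == pytest.approx(14.0)

    def test_first_altloc_kept(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        s = read_pdb(p)
        assert s.n_atoms == 2
        assert s.coords[0][0] == pytest.approx(11.0)

    def test_bad_record_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(MINIMAL_PDB.replace("A   1 ", "A   X "))
        with pytest.raises(PDBFormatError, match="line 1"):
            read_pdb(p)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(EmptyStructureError):
            read_pdb(p)

    def test_mismatched_model_rosters_raise(self, tmp_path):
        p = tmp_path / "mismatch.pdb"
        p.write_text(TWO_MODEL_PDB.replace("N1   DA A   1      11.000  12.000  14.000",
                                           "N3   DA A   1      11.000  12.000  14.000"))
        with pytest.raises(PDBFormatError):
            read_pdb(p)

    def test_write_read_idempotent_on_coordinates(self, tmp_path):
        s = build_base_step("GC", None)
        path = tmp_path / "step.pdb"
        write_pdb(s, path)
        r = read_pdb(path)
        assert r.n_atoms == s.n_atoms
        assert np.abs(r.coords - s.coords).max() < 1e-3  # PDB precision

    def test_multimodel_write_read(self, tmp_path):
        s = build_base_pair("A-T")
        traj = Structure(s.atoms, np.stack([s.coords, s.coords + 0.5]))
        path = tmp_path / "traj.pdb"
        write_pdb(traj, path)
        r = read_pdb(path)
        assert r.n_models == 2
        assert np.abs(r.models - traj.models).max() < 1e-3


class TestSelectAtoms:
    def test_cehs_subset_counts(self):
        pair = build_base_pair("A-T")
        sel = select_atoms(pair, "cehs-subset")
        by_res = {}
        for a in sel.atoms:
            by_res.setdefault(a.residue_id, []).append(a.name)
        # purine: C8, C4, N1, C1'; pyrimidine: N3, C6, C1'
        assert sorted(by_res["A:1"]) == ["C1'", "C4", "C8", "N1"]
        assert sorted(by_res["B:1"]) == ["C1'", "C6", "N3"]

    def test_all_heavy_is_identity_on_heavy_atoms(self):
        pair = build_base_pair("G-C")
        sel = select_atoms(pair, "all-heavy")
        assert sel.n_atoms == pair.n_atoms

    def test_base_c1p_on_generated_pair_is_identity(self):
        pair = build_base_pair("G-C")
        assert select_atoms(pair, "base+C1'").n_atoms == pair.n_atoms

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            select_atoms(build_base_pair("A-T"), "backbone")

    def test_missing_atom_skips_residue_with_warning(self):
        pair = build_base_pair("A-T")
        broken = pair.subset([i for i, a in enumerate(pair.atoms)
                              if not (a.residue_id == "A:1" and a.name == "C8")])
        with pytest.warns(UserWarning, match="C8"):
            sel = select_atoms(broken, "cehs-subset")
        assert set(a.residue_id for a in sel.atoms) == {"B:1"}


class TestGeneratorGeometry:
    def test_at_minimum_interbase_distance_is_hydrogen_bond_length(self, at_pair):
        rid = np.array(at_pair.residue_ids)
        D = np.linalg.norm(at_pair.coords[:, None] - at_pair.coords[None, :], axis=-1)
        inter = D[np.ix_(rid == "A:1", rid == "B:1")]
        assert 2.7 <= inter.min() <= 3.0

    def test_gc_has_three_hydrogen_bond_contacts(self, gc_pair):
        rid = np.array(gc_pair.residue_ids)
        D = np.linalg.norm(gc_pair.coords[:, None] - gc_pair.coords[None, :], axis=-1)
        inter = D[np.ix_(rid == "A:1", rid == "B:1")]
        assert int(np.sum(inter < 3.1)) == 3

    def test_stretch_translates_bases_apart(self):
        from lwph.cehs import HelicalParams

        base = build_base_pair("A-T")
        stretched = build_base_pair("A-T", HelicalParams(stretch=10.0))

        def min_inter(s):
            rid = np.array(s.residue_ids)
            D = np.linalg.norm(s.coords[:, None] - s.coords[None, :], axis=-1)
            return D[np.ix_(rid == "A:1", rid == "B:1")].min()

        assert min_inter(stretched) - min_inter(base) == pytest.approx(10.0, abs=0.05)

    def test_unknown_pair_type(self):
        with pytest.raises(ValueError):
            build_base_pair("A-G")

    def test_ring_cycle_ranks(self, at_pair):
        # bond graph at 1.7 A: purine contributes 2 independent cycles,
        # pyrimidine 1, so an A-T pair carries 3 rings in total
        total = 0
        for rid in at_pair.residues():
            idx = [i for i, a in enumerate(at_pair.atoms) if a.residue_id == rid]
            X = at_pair.coords[idx]
            D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
            adj = (D <= 1.7) & (D > 0)
            n_edges = int(adj.sum()) // 2
            n_comp = connected_components(csr_matrix(adj), directed=False)[0]
            cycles = n_edges - len(idx) + n_comp
            total += cycles
            assert cycles == (2 if at_pair.atoms[idx[0]].restype in "AG" else 1)
        assert total == 3


class TestDomains:
    def test_16mer_has_13_nonterminal_steps(self):
        duplex = build_duplex("ATGCATGCATGCATGC")
        domains = enumerate_local_domains(duplex, "base-step", exclude_terminal=True)
        assert len(domains) == 13
        assert all(len(d.residues) == 4 for d in domains)

    def test_16mer_keep_terminal_gives_15(self):
        duplex = build_duplex("ATGCATGCATGCATGC")
        assert len(enumerate_local_domains(duplex, "base-step", exclude_terminal=False)) == 15

    def test_2mer_nonterminal_is_empty(self):
        duplex = build_duplex("AT")
        assert enumerate_local_domains(duplex, "base-step", exclude_terminal=True) == []

    def test_steps_overlap_by_one_pair(self):
        duplex = build_duplex("ATGC")
        d = enumerate_local_domains(duplex, "base-step", exclude_terminal=False)
        assert len(set(d[0].residues) & set(d[1].residues)) == 2  # one shared pair

    def test_domains_cover_selected_atoms(self):
        duplex = build_duplex("ATGCAT")
        domains = enumerate_local_domains(duplex, "base-pair", exclude_terminal=False)
        covered = {i for dom in domains for i in dom.atom_indices}
        assert covered == set(range(duplex.n_atoms))

    def test_unequal_chains_raise(self):
        duplex = build_duplex("ATG")
        trimmed = duplex.subset([i for i, a in enumerate(duplex.atoms)
                                 if not (a.chain == "B" and a.resnum == 1)])
        with pytest.raises(PairingError):
            enumerate_local_domains(trimmed)

    def test_domain_json_manifest(self):
        duplex = build_duplex("ATGC")
        text = domains_to_json(enumerate_local_domains(duplex))
        import json

        payload = json.loads(text)
        assert payload[0]["label"].startswith("step")
        assert all(isinstance(i, int) for i in payload[0]["atom_indices"])
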