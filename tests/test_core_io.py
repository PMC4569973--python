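"""Structure/compound parsing and the admission filters."""

import textwrap

import numpy as np
import pytest

from bindscape import core_io
from bindscape.simulate import build_structure_text

BENZENE_SDF = """\
benzene
     RDKit          2D

  6  6  0  0  0  0  0  0  0  0999 V2000
    0.0000    1.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.8660    0.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.8660   -0.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000   -1.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8660   -0.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8660    0.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
M  END
$$$$
"""

RGROUP_SDF = """\
rgroup entry
     RDKit          2D

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000    0.0000    0.0000 R#  0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
M  END
$$$$
"""


def write_structure(tmp_path, name="s1.pdb", resolution=1.8, n_pocket=4):
    pocket = [("A", 3.5)] * n_pocket
    text = build_structure_text(name[:-4], "LIG", pocket,
                                ["G"] * 10, resolution=resolution)
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadStructure:
    def test_roundtrip_counts(self, tmp_path):
        path = write_structure(tmp_path)
        model = core_io.read_structure(path)
        assert len(model.chains) == 1
        assert len(model.chains[0]) == 14
        assert len(model.ligands) == 1
        assert model.ligands[0].compound_id == "LIG"

    def test_two_chains_one_ligand(self, tmp_path):
        # hand-built file: two chains, one het group
        text = textwrap.dedent("""\
            ATOM      1  CA  ALA A   1      20.000   0.000   0.000  1.00  0.00           C
            ATOM      2  CA  GLY A   2      23.000   0.000   0.000  1.00  0.00           C
            TER
            ATOM      3  CA  HIS B   1       0.000  20.000   0.000  1.00  0.00           C
            TER
            HETATM    4  C1  XYZ A 901       0.000   0.000   0.000  1.00  0.00           C
            HETATM    5  O1  XYZ A 901       1.200   0.000   0.000  1.00  0.00           O
            END
            """)
        path = tmp_path / "two.pdb"
        path.write_text(text)
        model = core_io.read_structure(path)
        assert len(model.chains) == 2
        assert len(model.ligands) == 1
        assert model.resolution is None

    def test_resolution_parsed(self, tmp_path):
        model = core_io.read_structure(write_structure(tmp_path, resolution=2.0))
        assert model.resolution == pytest.approx(2.0)

    def test_missing_resolution(self, tmp_path):
        model = core_io.read_structure(
            write_structure(tmp_path, resolution=None))
        assert model.resolution is None

    def test_hydrogens_flagged_not_heavy(self):
        atom = core_io.Atom("H1", "H", np.zeros(3), is_heavy=False)
        assert not atom.is_heavy

    def test_unparsable_file(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("")
        with pytest.raises(core_io.StructureFormatError):
            core_io.read_structure(bad)


class TestFilterStructures:
    @pytest.mark.parametrize("resolution,kept", [
        (2.0, True),    # "2 A or better" is inclusive
        (1.5, True),
        (2.5, False),
        (None, False),  # no record cannot satisfy the bound
    ])
    def test_resolution_bound(self, tmp_path, resolution, kept):
        model = core_io.read_structure(
            write_structure(tmp_path, resolution=resolution))
        out = core_io.filter_structures([model])
        assert (len(out) == 1) is kept

    def test_idempotent(self, tmp_path):
        ms = [core_io.read_structure(write_structure(tmp_path, f"s{i}.pdb",
                                                     resolution=r))
              for i, r in enumerate([1.5, 2.0, 2.5])]
        once = core_io.filter_structures(ms)
        assert core_io.filter_structures(once) == once


class TestIdentifyLigands:
    def _model_with_ligand(self, mw_atoms, compound_id="LIG", covalent=False):
        atoms = [core_io.Atom(f"X{i}", el, np.array([30.0 + i, 0, 0]), True)
                 for i, el in enumerate(mw_atoms)]
        lig = core_io.LigandInstance(compound_id, "s", "A", "901", atoms,
                                     core_io._ligand_weight(atoms),
                                     covalent_flag=covalent)
        chain = core_io.TargetChain("s", "A", [core_io.Residue(
            "A", "1", "A", [core_io.Atom("CA", "C", np.zeros(3), True)])])
        return core_io.StructureModel("s", 1.5, [chain], [lig])

    def test_small_compound_excluded(self):
        model = self._model_with_ligand(["C", "O"])   # ~28 Da < 30
        assert core_io.identify_ligands(model) == []

    def test_large_compound_excluded(self):
        model = self._model_with_ligand(["I"] * 8)    # > 1000 Da
        assert core_io.identify_ligands(model) == []

    def test_solvent_code_excluded(self):
        model = self._model_with_ligand(["O"] * 4, compound_id="HOH")
        assert core_io.identify_ligands(model) == []

    def test_covalent_excluded(self):
        model = self._model_with_ligand(["C"] * 6, covalent=True)
        assert core_io.identify_ligands(model) == []

    def test_kept_ligand_satisfies_predicates(self):
        model = self._model_with_ligand(["C"] * 6)
        out = core_io.identify_ligands(model)
        assert out == [model.ligands[0]]
        for lig in out:
            assert 30 <= lig.molecular_weight <= 1000
            assert lig.compound_id not in core_io.DEFAULT_EXCLUSIONS
            assert not lig.covalent_flag

    def test_covalent_flag_from_geometry(self, tmp_path):
        # contact distances of 3.2+ A in generated files: never covalent
        model = core_io.read_structure(write_structure(tmp_path))
        assert not model.ligands[0].covalent_flag


class TestReadCompoundLibrary:
    def test_benzene_weight(self, tmp_path):
        p = tmp_path / "benzene.sdf"
        p.write_text(BENZENE_SDF)
        recs = core_io.read_compound_library(p)
        assert len(recs) == 1
        assert recs[0].molecular_weight == pytest.approx(78.11, abs=0.01)
        assert recs[0].smiles == "c1ccccc1"

    def test_rgroup_entry_dropped(self, tmp_path):
        p = tmp_path / "lib.sdf"
        p.write_text(RGROUP_SDF + BENZENE_SDF)
        recs = core_io.read_compound_library(p)
        assert [r.compound_id for r in recs] == ["benzene"]

    def test_empty_library_error(self, tmp_path):
        p = tmp_path / "empty.sdf"
        p.write_text("")
        with pytest.raises(core_io.EmptyLibraryError):
            core_io.read_compound_library(p)
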