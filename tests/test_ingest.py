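"""Table reading, structure standardization, and group expansion."""

from __future__ import annotations

import textwrap

import pytest
from hypothesis import given, settings, strategies as hst
from rdkit import Chem

from promiscuitrack.ingest import (
    Dialect,
    expand_target_groups,
    read_activity_table,
    read_drug_table,
    standardize_structure,
)

ACTIVITY_HEADER = (
    "compound_id\tsmiles\ttarget_id\ttarget_family\trelationship_type\t"
    "confidence_score\tmeasurement_type\trelation\tvalue\tunits\tyear"
)


def write_activity(tmp_path, rows, header=ACTIVITY_HEADER):
    path = tmp_path / "activities.tsv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


class TestStandardizeStructure:
    def test_kekule_and_aromatic_forms_agree(self):
        assert standardize_structure("C1=CC=CC=C1") == standardize_structure("c1ccccc1")

    def test_salt_reduced_to_largest_organic_fragment(self):
        # sodium acetate → neutral acetic acid, counter-ion stripped
        assert standardize_structure("CC(=O)[O-].[Na+]") == standardize_structure(
            "CC(=O)O"
        )

    def test_unparsable_smiles_flagged_invalid(self):
        assert standardize_structure("C1CC") is None  # unclosed ring

    @pytest.mark.parametrize(
        "smiles", ["CCO", "c1ccc(O)cc1", "CC(=O)Nc1ccc(O)cc1", "O=C1CSC(=S)N1CC"]
    )
    def test_idempotent(self, smiles):
        once = standardize_structure(smiles)
        assert standardize_structure(once) == once

    @pytest.mark.parametrize("seed", range(5))
    def test_atom_order_invariance(self, seed):
        """Permuting input atom order never changes the canonical string."""
        import random

        mol = Chem.MolFromSmiles("CC(=O)Nc1ccc(O)cc1")
        order = list(range(mol.GetNumAtoms()))
        random.Random(seed).shuffle(order)
        shuffled = Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)
        assert standardize_structure(shuffled) == standardize_structure(
            "CC(=O)Nc1ccc(O)cc1"
        )


class TestReadActivityTable:
    def test_well_formed_rows_all_read(self, tmp_path):
        rows = [
            "C1\tCCO\tP1\tFAM01\tD\t9\tKi\t=\t50\tnM\t2005",
            "C1\tCCO\tP2\tFAM01\tD\t9\tIC50\t=\t2\tuM\t2006",
            "C2\tCCN\tP1\tFAM01\tD\t9\tKi\t=\t10\tnM\t2007",
        ]
        records, log = read_activity_table(write_activity(tmp_path, rows))
        assert len(records) == 3 and log.empty

    def test_unit_conversion_to_nM(self, tmp_path):
        rows = ["C1\tCCO\tP1\t\tD\t9\tIC50\t=\t2\tuM\t2006"]
        records, _ = read_activity_table(write_activity(tmp_path, rows))
        assert records[0].value_nM == pytest.approx(2000.0)

    def test_unparsable_year_dropped_and_logged(self, tmp_path):
        rows = [
            "C1\tCCO\tP1\t\tD\t9\tKi\t=\t50\tnM\tn/a",
            "C2\tCCN\tP1\t\tD\t9\tKi\t=\t10\tnM\t2007",
        ]
        records, log = read_activity_table(write_activity(tmp_path, rows))
        assert len(records) == 1
        assert len(log) == 1 and log.iloc[0]["reason"] == "unparsable year"

    def test_conservation_rows_equal_records_plus_rejections(self, tmp_path):
        rows = [
            "C1\tCCO\tP1\t\tD\t9\tKi\t=\t50\tnM\t2005",
            "C2\tC1CC\tP1\t\tD\t9\tKi\t=\t10\tnM\t2005",  # bad structure
            "C3\tCCN\tP1\t\tD\t9\tKi\t=\tNaNope\tnM\t2005",  # bad value
            "C4\tCCS\tP2\t\tD\t9\tKi\t=\t7\tnM\t2008",
        ]
        records, log = read_activity_table(write_activity(tmp_path, rows))
        assert len(records) + len(log) == len(rows)

    def test_blank_relation_treated_as_equals(self, tmp_path):
        rows = ["C1\tCCO\tP1\t\tD\t9\tKi\t\t50\tnM\t2005"]
        records, _ = read_activity_table(write_activity(tmp_path, rows))
        assert records[0].relation == "="

    def test_missing_required_column_fatal(self, tmp_path):
        header = ACTIVITY_HEADER.replace("\ttarget_id", "")
        rows = ["C1\tCCO\t\tD\t9\tKi\t=\t50\tnM\t2005"]
        with pytest.raises(ValueError, match="target_id"):
            read_activity_table(write_activity(tmp_path, rows, header=header))

    def test_empty_file_fatal(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(ACTIVITY_HEADER + "\n")
        with pytest.raises(ValueError, match="empty"):
            read_activity_table(path)

    def test_dialect_renames_columns(self, tmp_path):
        header = ACTIVITY_HEADER.replace("smiles", "canonical_smiles").replace(
            "year", "release_year"
        )
        rows = ["C1\tCCO\tP1\t\tD\t9\tKi\t=\t50\tnM\t2005"]
        dialect = Dialect(
            activity={"smiles": "canonical_smiles", "year": "release_year"}
        )
        records, log = read_activity_table(
            write_activity(tmp_path, rows, header=header), dialect
        )
        assert len(records) == 1 and records[0].year == 2005


class TestExpandTargetGroups:
    def test_seven_member_receptor_group_expands_to_seven(self):
        # e.g. an NMDA-receptor annotation carrying seven subunit accessions
        group = "|".join(f"P{i}" for i in range(7))
        ann = expand_target_groups("D1", "atomoxetine-like", "CCO", "drug-action target", group)
        assert len(ann.target_ids) == 7

    def test_singleton_group(self):
        ann = expand_target_groups("D1", "x", "CCO", "carrier", "P1")
        assert ann.target_ids == frozenset({"P1"})

    def test_duplicate_members_deduplicated(self):
        ann = expand_target_groups("D1", "x", "CCO", "carrier", "P1|P1")
        assert len(ann.target_ids) == 1

    def test_empty_group_dropped(self):
        assert expand_target_groups("D1", "x", "CCO", "carrier", "") is None


class TestReadDrugTable:
    def test_reads_and_expands(self, tmp_path):
        path = tmp_path / "drugs.tsv"
        path.write_text(
            textwrap.dedent(
                """\
                drug_id\tname\tsmiles\tcategory\ttarget_group
                D1\talpha\tCCO\tdrug-action target\tP1|P2
                D1\talpha\tCCO\ttransporter\tP3
                D2\tbeta\tC1CC\tcarrier\tP4
                """
            )
        )
        annotations, log = read_drug_table(path)
        assert len(annotations) == 2  # D2 has an invalid structure
        assert {len(a.target_ids) for a in annotations} == {1, 2}
        assert log.iloc[0]["reason"] == "invalid structure"


@settings(derandomize=True, max_examples=30)
@given(
    smiles=hst.sampled_from(
        ["CCO", "CCN", "c1ccccc1O", "CC(C)Cc1ccc(C)cc1C(C)C(=O)O", "OC(=O)c1ccccc1O"]
    )
)
def test_canonicalization_is_a_congruence(smiles):
    """Structures are matched downstream iff canonical strings are equal;
    re-standardizing any canonical output is a fixed point."""
    canonical = standardize_structure(smiles)
    assert canonical is not None
    assert standardize_structure(canonical) == canonical
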