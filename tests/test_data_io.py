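"""Annotation tables, identification rule, activity labels, compound sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytonox import datasets
from phytonox.data_io import (
    ACTIVE,
    EXCLUDED,
    NOT_ACTIVE,
    CompoundRecord,
    IdentificationPolicy,
    IntensityMatrix,
    LabelPolicy,
    MetaboliteRecord,
    assign_activity_labels,
    load_compound_set,
    load_metabolite_table,
    tentative_identify,
    write_compound_set,
    write_metabolite_table,
)
from phytonox.errors import ConfigurationError, FormatError


@pytest.fixture(scope="module")
def annotations():
    return datasets.metabolite_annotations()


@pytest.fixture(scope="module")
def malic(annotations):
    return next(r for r in annotations if r.name == "Malic acid")


class TestMetaboliteTable:
    def test_bundled_table_counts(self, annotations):
        assert len(annotations) == 36
        assert sum(r.in_fruit for r in annotations) == 25
        assert sum(r.in_leaf for r in annotations) == 22

    def test_first_row_fields(self, malic):
        assert malic.precursor_mz == 133.12
        assert malic.in_fruit and malic.in_leaf
        assert malic.fragments == (115.31, 89.30, 71.22)

    def test_round_trip(self, annotations, tmp_path):
        path = tmp_path / "table.csv"
        write_metabolite_table(annotations, path)
        assert load_metabolite_table(path) == annotations

    def test_round_trip_tsv(self, annotations, tmp_path):
        path = tmp_path / "table.tsv"
        write_metabolite_table(annotations, path)
        assert load_metabolite_table(path) == annotations

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(FormatError):
            load_metabolite_table(path)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("name,group,mw\nA,B,1.0\n")
        with pytest.raises(FormatError, match="precursor_mz"):
            load_metabolite_table(path)

    def test_bad_presence_code_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "name,group,mw,precursor_mz,fragments,rt,presence\n"
            "A,B,100,99,50;40,1.0,yes/no\n"
        )
        with pytest.raises(FormatError, match="row 0"):
            load_metabolite_table(path)

    def test_record_invariants(self):
        with pytest.raises(FormatError):
            MetaboliteRecord("x", "g", 100.0, -1.0, (50.0,), 1.0, True, False)
        with pytest.raises(FormatError):
            MetaboliteRecord("x", "g", 100.0, 99.0, (), 1.0, True, False)
        with pytest.warns(UserWarning, match="inconsistent"):
            MetaboliteRecord("x", "g", 90.0, 99.0, (50.0,), 1.0, True, False)


class TestTentativeIdentify:
    def test_worked_example_identifies(self, malic):
        result = tentative_identify(133.12, [115.31, 89.30], malic)
        assert result.identified
        assert result.n_matched_fragments == 2
        assert result.precursor_delta == 0.0

    def test_single_fragment_rejected(self, malic):
        assert not tentative_identify(133.12, [115.31], malic).identified

    def test_precursor_within_tolerance(self, malic):
        result = tentative_identify(133.05, [115.31, 89.30], malic)
        assert result.identified
        assert result.precursor_delta == pytest.approx(0.07)

    def test_precursor_outside_tolerance(self, malic):
        assert not tentative_identify(133.30, [115.31, 89.30], malic).identified

    def test_each_reference_fragment_matched_once(self, malic):
        # two observed ions near one reference fragment: only one pairs
        result = tentative_identify(133.12, [115.30, 115.35], malic)
        assert result.n_matched_fragments == 1
        assert not result.identified

    def test_invalid_policy(self):
        with pytest.raises(ConfigurationError):
            IdentificationPolicy(ms_tol=0.0)
        with pytest.raises(ConfigurationError):
            IdentificationPolicy(min_fragments=0)

    @settings(max_examples=50, deadline=None)
    @given(
        precursor=st.floats(130.0, 136.0),
        frags=st.lists(st.floats(60.0, 120.0), min_size=0, max_size=5),
        scale=st.floats(1.0, 5.0),
    )
    def test_monotone_in_tolerances(self, malic, precursor, frags, scale):
        """Enlarging tolerances never flips identified -> not identified."""
        tight = IdentificationPolicy()
        loose = IdentificationPolicy(ms_tol=tight.ms_tol * scale, msms_tol=tight.msms_tol * scale)
        if tentative_identify(precursor, frags, malic, tight).identified:
            assert tentative_identify(precursor, frags, malic, loose).identified


class TestActivityLabels:
    @pytest.mark.parametrize(
        "ic50, expected",
        [
            (50e-9, ACTIVE),
            (150e-6, NOT_ACTIVE),
            (99.5e-6, EXCLUDED),  # the printed 99-100 uM gap
            (10e-9, EXCLUDED),    # below the active window
        ],
    )
    def test_examples(self, ic50, expected):
        assert assign_activity_labels([ic50]) == [expected]

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            assign_activity_labels([0.0])

    def test_invalid_policy(self):
        with pytest.raises(ConfigurationError):
            LabelPolicy(active_low=1e-3, active_high=1e-6)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(1e-12, 1e-2))
    def test_partition(self, ic50):
        """Every positive IC50 maps to exactly one class."""
        [label] = assign_activity_labels([ic50])
        assert label in {ACTIVE, NOT_ACTIVE, EXCLUDED}


class TestCompoundSet:
    def test_bundled_queries(self):
        records = datasets.query_compounds()
        assert len(records) == 24
        assert all(r.mol() is not None for r in records)

    def test_malic_acid_heavy_atoms(self):
        record = CompoundRecord("malic", "OC(CC(O)=O)C(O)=O")
        assert record.mol().GetNumHeavyAtoms() == 9

    def test_unclosed_ring_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,smiles\nok,CCO\nbroken,C1CC\n")
        with pytest.raises(FormatError, match="broken"):
            load_compound_set(path)
        lenient = load_compound_set(path, strict=False)
        assert [r.id for r in lenient] == ["ok"]

    def test_round_trip_with_labels(self, tmp_path):
        records = [
            CompoundRecord("a", "CCO", ACTIVE, 1e-6),
            CompoundRecord("b", "c1ccccc1", NOT_ACTIVE, 2e-4),
        ]
        path = tmp_path / "set.csv"
        write_compound_set(records, path)
        assert load_compound_set(path) == records

    def test_label_policy_applied(self, tmp_path):
        path = tmp_path / "set.csv"
        path.write_text("id,smiles,ic50\na,CCO,5e-08\nb,CCN,2e-04\n")
        records = load_compound_set(path, label_policy=LabelPolicy())
        assert [r.label for r in records] == [ACTIVE, NOT_ACTIVE]


class TestIntensityMatrix:
    def _frame(self, values):
        index = pd.MultiIndex.from_tuples(
            [("fruit", 1, 1), ("fruit", 1, 2), ("fruit", 4, 1), ("fruit", 4, 2)],
            names=("tissue", "day", "replicate"),
        )
        return pd.DataFrame(values, index=index, columns=["m1"])

    def test_positive_values_enforced(self):
        with pytest.raises(FormatError, match="positive"):
            IntensityMatrix(self._frame([[1.0], [2.0], [0.0], [3.0]]))

    def test_duplicate_keys_rejected(self):
        frame = self._frame([[1.0], [2.0], [3.0], [4.0]])
        bad = pd.concat([frame, frame.iloc[[0]]])
        with pytest.raises(FormatError, match="duplicate"):
            IntensityMatrix(bad)

    def test_unbalanced_replicates_rejected(self):
        frame = self._frame([[1.0], [2.0], [3.0], [4.0]]).iloc[:3]
        with pytest.raises(FormatError, match="unbalanced"):
            IntensityMatrix(frame)

    def test_csv_round_trip(self, tmp_path):
        matrix = IntensityMatrix(self._frame([[1.5], [2.5], [3.5], [4.5]]))
        path = tmp_path / "m.csv"
        matrix.to_csv(path)
        back = IntensityMatrix.from_csv(path)
        pd.testing.assert_frame_equal(back.data, matrix.data)
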