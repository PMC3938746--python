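"""Labelled dataset conversion, sidecar persistence, subject rows."""

import pytest

from odmconvert import (
    SynthSpec, canonicalize, count_codes, from_stats, generate_model,
    load_stats, save_stats, to_stats, write_odm,
)
from odmconvert.odm import OdmDocument
from odmconvert.stats import Column, LabelledDataset, StatsFormatError, \
    attach_clinical_data


class TestToStats:
    def test_columns_are_item_oids_in_order(self, model):
        ds = to_stats(model)
        assert [c.column_id for c in ds.columns] == [
            f"I.{k:03d}" for k in range(1, 9)]
        assert ds.n_rows == 0

    def test_gender_value_labels(self, model):
        ds = to_stats(model)
        assert ds.value_labels["I.004"] == {"1": "male", "2": "female"}
        assert ds.variable_labels["I.004"] == "Gender"

    def test_storage_classes(self, model):
        ds = to_stats(model)
        assert [c.storage_type for c in ds.columns] == [
            "logical", "integer", "text", "integer", "text", "text",
            "real", "text"]

    def test_study_attributes_from_header(self, model):
        attrs = to_stats(model).study_attributes
        assert attrs["StudyName"] == "ODM Test Study"
        assert attrs["Sponsor"] == "Testsponsor"
        assert attrs["Form"] == "ODM-Test"

    def test_empty_model_keeps_attributes_only(self):
        from odmconvert import StudyModel
        ds = to_stats(StudyModel())
        assert ds.columns == [] and ds.study_attributes["StudyOID"] == "S.0000"

    def test_unknown_language_rejected(self, model):
        with pytest.raises(StatsFormatError, match="fr"):
            to_stats(model, language="fr")


class TestFromStats:
    def test_round_trip_preserves_all_codes(self, model):
        back = from_stats(to_stats(model))
        assert back == canonicalize(model)
        assert count_codes(back) == 12

    def test_bare_unlabelled_column_becomes_string_item(self):
        ds = LabelledDataset(columns=[Column("X", "text")])
        m = from_stats(ds)
        assert m.groups[0].name == "Ungrouped" and m.groups[0].oid == "IG.1"
        item = m.groups[0].items[0]
        assert item.name == "X" and item.datatype == "string"

    def test_duplicate_column_ids_rejected(self):
        ds = LabelledDataset(columns=[Column("X", "text"), Column("X", "text")])
        with pytest.raises(StatsFormatError, match="duplicate"):
            from_stats(ds)

    def test_value_labels_on_missing_column_rejected(self):
        ds = LabelledDataset(columns=[Column("X", "text")],
                             value_labels={"Y": {"1": "yes"}})
        with pytest.raises(StatsFormatError, match="Y"):
            from_stats(ds)

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_projection_is_stable(self, seed):
        m = generate_model(SynthSpec(seed=seed))
        ds = to_stats(m)
        assert to_stats(from_stats(ds)) == ds


class TestPersistence:
    @pytest.mark.parametrize("seed", [3, 7])
    def test_save_load_identity(self, tmp_path, seed):
        ds = to_stats(generate_model(SynthSpec(seed=seed)))
        save_stats(ds, tmp_path / "study")
        assert load_stats(tmp_path / "study") == ds

    def test_save_load_identity_with_rows(self, tmp_path, model):
        ds = attach_clinical_data(to_stats(model), _clinical_doc(model))
        save_stats(ds, tmp_path / "study.csv")
        assert load_stats(tmp_path / "study.csv") == ds

    def test_foreign_sidecar_rejected(self, tmp_path):
        (tmp_path / "x.meta.json").write_text('{"format": "other"}')
        (tmp_path / "x.csv").write_text("a\n")
        with pytest.raises(StatsFormatError, match="sidecar"):
            load_stats(tmp_path / "x")


def _clinical_doc(model, values=None):
    doc = write_odm(model)
    if values is None:
        values = [
            {"I.001": "true", "I.002": "34", "I.004": "2", "I.007": "1.2"},
            {"I.001": "false", "I.004": "1"},
        ]
    subjects = []
    for k, row in enumerate(values, start=1):
        items = "".join(f'<ItemData ItemOID="{o}" Value="{v}"/>'
                        for o, v in row.items())
        subjects.append(
            f'<SubjectData SubjectKey="P{k}"><StudyEventData StudyEventOID="SE.1">'
            f'<FormData FormOID="F.1"><ItemGroupData ItemGroupOID="IG.1">'
            f'{items}</ItemGroupData></FormData></StudyEventData></SubjectData>')
    clinical = (f'<ClinicalData StudyOID="S.0000" MetaDataVersionOID="MDV.1">'
                f'{"".join(subjects)}</ClinicalData></ODM>')
    return OdmDocument(doc.xml_text.replace("</ODM>", clinical))


class TestAttachClinicalData:
    def test_one_row_per_subject(self, model):
        ds = attach_clinical_data(to_stats(model), _clinical_doc(model))
        assert ds.n_rows == 2
        assert ds.column("I.001").values == [True, False]
        assert ds.column("I.002").values == [34, None]
        assert ds.column("I.007").values == [1.2, None]

    def test_coded_value_stays_resolvable(self, model):
        ds = attach_clinical_data(to_stats(model), _clinical_doc(model))
        stored = ds.column("I.004").values[1]
        assert stored == 1
        assert ds.value_labels["I.004"][str(stored)] == "male"

    def test_document_without_clinical_data_is_noop(self, model):
        ds = to_stats(model)
        assert attach_clinical_data(ds, write_odm(model)) == ds

    def test_unknown_item_oid_dropped_with_warning(self, model, caplog):
        doc = _clinical_doc(model, values=[{"I.999": "5"}])
        with caplog.at_level("WARNING"):
            ds = attach_clinical_data(to_stats(model), doc)
        assert ds.n_rows == 1 and ds.column("I.001").values == [None]
        assert any("I.999" in r.message for r in caplog.records)

    def test_uncoercible_value_names_subject_and_item(self, model):
        doc = _clinical_doc(model, values=[{"I.002": "abc"}])
        with pytest.raises(StatsFormatError, match=r"P1.*I\.002"):
            attach_clinical_data(to_stats(model), doc)
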