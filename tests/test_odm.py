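"""ODM 1.3 serialization and lenient parsing."""

from datetime import datetime, timezone

import pytest
from lxml import etree

from odmconvert import (
    StudyModel, SynthSpec, canonicalize, count_codes, generate_model,
    read_odm, write_odm,
)
from odmconvert.odm import ODM_NS, OdmDocument, OdmFormatError

Q = "{%s}" % ODM_NS


def elements(doc, tag):
    return doc.root().findall(f".//{Q}{tag}")


class TestWriteOdm:
    def test_worked_example_counts(self, model):
        doc = write_odm(model)
        assert len(elements(doc, "ItemDef")) == 8
        assert len(elements(doc, "ItemGroupDef")) == 1
        assert len(elements(doc, "CodeList")) == 1
        assert len(elements(doc, "CodeListItem")) == 2

    def test_male_value_carries_snomed_alias(self, model):
        doc = write_odm(model)
        male = next(e for e in elements(doc, "CodeListItem")
                    if e.get("CodedValue") == "1")
        aliases = {(a.get("Context"), a.get("Name"))
                   for a in male.findall(Q + "Alias")}
        assert ("SNOMED CT 2010_0731", "248153007") in aliases
        assert ("UMLS CUI", "C0024554") in aliases

    def test_every_code_is_exactly_one_alias(self, model):
        doc = write_odm(model)
        assert len(elements(doc, "Alias")) == count_codes(model) == 12

    def test_envelope_attributes(self, model):
        root = write_odm(model, datetime(2014, 2, 28, tzinfo=timezone.utc)).root()
        assert root.get("FileType") == "Snapshot"
        assert root.get("ODMVersion") == "1.3.1"
        assert root.get("CreationDateTime") == "2014-02-28T00:00:00+00:00"
        study = root.find(Q + "Study")
        assert study.get("OID") == "S.0000"

    def test_empty_model_still_has_form(self):
        doc = write_odm(StudyModel())
        assert len(elements(doc, "FormDef")) == 1
        assert elements(doc, "ItemGroupDef") == []

    def test_output_is_well_formed(self, model):
        etree.fromstring(write_odm(model).xml_text.encode())


class TestReadOdm:
    def test_round_trip_equals_canonical_fixture(self, model):
        assert read_odm(write_odm(model)) == canonicalize(model)

    def test_question_text_and_code_recovered(self, model):
        m = read_odm(write_odm(model))
        first = next(m.items())
        assert first.labels["en"] == "Willingness to participate in clinical trials"
        assert ("UMLS CUI", "C1516879") in {(c.terminology, c.code)
                                            for c in first.codes}

    def test_empty_metadataversion_is_empty_model(self):
        xml = (f'<ODM xmlns="{ODM_NS}"><Study OID="S.1">'
               '<MetaDataVersion OID="M" Name="m"/></Study></ODM>')
        m = read_odm(OdmDocument(xml))
        assert m.groups == [] and m.header.study_oid == "S.1"

    @pytest.mark.parametrize("xml, fragment", [
        ("<ODM><oops", "not well-formed"),
        ('<Other xmlns="urn:x"/>', "namespace"),
        (f'<ODM xmlns="{ODM_NS}"><Study OID="S"/></ODM>', "MetaDataVersion"),
        (f'<ODM xmlns="{ODM_NS}"/>', "no Study"),
    ])
    def test_structural_defects_raise(self, xml, fragment):
        with pytest.raises(OdmFormatError, match=fragment):
            read_odm(OdmDocument(xml))

    def test_foreign_datatypes_mapped_with_warning(self, caplog):
        xml = (f'<ODM xmlns="{ODM_NS}"><Study OID="S">'
               '<MetaDataVersion OID="M" Name="m">'
               '<FormDef OID="F" Name="f" Repeating="No">'
               '<ItemGroupRef ItemGroupOID="G" Mandatory="No"/></FormDef>'
               '<ItemGroupDef OID="G" Name="g" Repeating="No">'
               '<ItemRef ItemOID="A" Mandatory="No"/>'
               '<ItemRef ItemOID="B" Mandatory="No"/></ItemGroupDef>'
               '<ItemDef OID="A" Name="a" DataType="datetime"/>'
               '<ItemDef OID="B" Name="b" DataType="double"/>'
               '</MetaDataVersion></Study></ODM>')
        with caplog.at_level("WARNING"):
            m = read_odm(OdmDocument(xml))
        assert [it.datatype for it in m.items()] == ["string", "float"]
        assert sum("DataType" in r.message for r in caplog.records) == 2

    def test_multiple_forms_parses_first_with_warning(self, caplog):
        xml = (f'<ODM xmlns="{ODM_NS}"><Study OID="S">'
               '<MetaDataVersion OID="M" Name="m">'
               '<FormDef OID="F1" Name="first" Repeating="No"/>'
               '<FormDef OID="F2" Name="second" Repeating="No"/>'
               '</MetaDataVersion></Study></ODM>')
        with caplog.at_level("WARNING"):
            m = read_odm(OdmDocument(xml))
        assert m.header.form_name == "first"
        assert any("forms" in r.message for r in caplog.records)

    def test_sponsor_condition_survive_description_carrier(self, model):
        m = read_odm(write_odm(model))
        assert m.header.sponsor == "Testsponsor"
        assert m.header.condition == "Testcondition"
        assert m.header.study_description == "Test of ODM tools"

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_round_trip_on_synthetic_models(self, seed):
        m = generate_model(SynthSpec(seed=seed))
        assert read_odm(write_odm(m)) == canonicalize(m)
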