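"""CDISC ODM 1.3 metadata serialization and parsing.

A study model becomes one ODM ``Study`` with a single ``MetaDataVersion``
holding one ``FormDef``, its ``ItemGroupDef``/``ItemDef`` tree and the
``CodeList`` definitions.  Semantic annotations ride on ``Alias`` elements
(``Context`` = terminology designation, ``Name`` = code value) attached to
item groups, items and code-list entries — the standard vehicle for
terminology codes in ODM metadata.

Two header fields of the office template, Sponsor and Condition, have no
native ODM 1.3 slot.  They are carried as reversible ``Sponsor: …`` /
``Condition: …`` lines prefixed to ``GlobalVariables/StudyDescription``
and stripped again on read; study contact details go to an
``AdminData/User`` record.  This keeps documents schema-valid while
preserving the round trip.

Foreign documents (written by other tools) are read leniently: absent
aliases and decodes are fine, unknown datatypes are mapped to the nearest
supported one with a logged warning, and scheduling/measurement metadata
outside the form tree is ignored with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

from lxml import etree

from .model import (
    DATATYPES, CodeList, CodeListItem, Item, ItemGroup, SemanticCode,
    StudyHeader, StudyModel, canonicalize,
)

log = logging.getLogger(__name__)

ODM_NS = "http://www.cdisc.org/ns/odm/v1.3"
NSMAP = {None: ODM_NS}
_Q = "{%s}" % ODM_NS
XML_LANG = "{http://www.w3.org/XML/1998/namespace}lang"

#: Nearest-supported mapping applied to foreign DataType values.
FOREIGN_DATATYPES = {
    "text": "string",
    "datetime": "string",
    "double": "float",
    "partialDate": "string",
    "partialTime": "string",
    "partialDatetime": "string",
    "intervalDatetime": "string",
    "durationDatetime": "string",
    "incompleteDatetime": "string",
    "URI": "string",
    "base64Binary": "string",
    "hexBinary": "string",
}

_IGNORED_METADATA = ("MeasurementUnit", "RangeCheck", "ConditionDef",
                     "MethodDef", "StudyEventDef")


class OdmFormatError(ValueError):
    """The document is not a usable ODM 1.3 metadata file."""


@dataclass
class OdmDocument:
    """A serialized ODM 1.3 XML document."""

    xml_text: str

    def root(self) -> etree._Element:
        try:
            return etree.fromstring(self.xml_text.encode("utf-8"))
        except etree.XMLSyntaxError as exc:
            raise OdmFormatError(f"not well-formed XML: {exc}") from exc

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.xml_text, encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "OdmDocument":
        return cls(Path(path).read_text(encoding="utf-8"))


def _translated(parent: etree._Element, tag: str, texts: dict[str, str],
                languages: list[str]) -> None:
    """Append <tag><TranslatedText xml:lang=…>…</…> in model language order."""
    if not texts:
        return
    el = etree.SubElement(parent, _Q + tag)
    langs = [l for l in languages if l in texts]
    langs += [l for l in texts if l not in langs]
    for lang in langs:
        tt = etree.SubElement(el, _Q + "TranslatedText")
        tt.set(XML_LANG, lang)
        tt.text = texts[lang]


def _aliases(parent: etree._Element, codes: list[SemanticCode]) -> None:
    for sc in codes:
        etree.SubElement(parent, _Q + "Alias",
                         Context=sc.terminology, Name=sc.code)


def write_odm(model: StudyModel, creation_time: datetime | None = None) -> OdmDocument:
    """Serialize a study model as a CDISC ODM 1.3 Snapshot metadata document.

    ``creation_time`` is injectable so output is reproducible in tests;
    it defaults to the current UTC time.
    """
    if creation_time is None:
        creation_time = datetime.now(timezone.utc)
    h = model.header
    root = etree.Element(
        _Q + "ODM", nsmap=NSMAP,
        FileOID=f"{h.study_oid}.export", FileType="Snapshot",
        Granularity="Metadata", ODMVersion="1.3.1",
        CreationDateTime=creation_time.isoformat(timespec="seconds"))
    study = etree.SubElement(root, _Q + "Study", OID=h.study_oid)
    gv = etree.SubElement(study, _Q + "GlobalVariables")
    etree.SubElement(gv, _Q + "StudyName").text = h.study_name
    description = (f"Sponsor: {h.sponsor}\nCondition: {h.condition}\n"
                   f"{h.study_description}")
    etree.SubElement(gv, _Q + "StudyDescription").text = description
    etree.SubElement(gv, _Q + "ProtocolName").text = h.form_name

    mdv = etree.SubElement(study, _Q + "MetaDataVersion", OID="MDV.1",
                           Name=h.study_name or h.form_name)
    form = etree.SubElement(mdv, _Q + "FormDef", OID=model.form_oid,
                            Name=h.form_name, Repeating="No")
    for group in model.groups:
        etree.SubElement(form, _Q + "ItemGroupRef", ItemGroupOID=group.oid,
                         Mandatory="No")
    for group in model.groups:
        igd = etree.SubElement(mdv, _Q + "ItemGroupDef", OID=group.oid,
                               Name=group.name, Repeating="No")
        _translated(igd, "Description", group.labels, model.languages)
        for item in group.items:
            etree.SubElement(igd, _Q + "ItemRef", ItemOID=item.oid,
                             Mandatory="No")
        _aliases(igd, group.codes)
    for item in model.items():
        idef = etree.SubElement(mdv, _Q + "ItemDef", OID=item.oid,
                                Name=item.name, DataType=item.datatype)
        _translated(idef, "Question", item.labels, model.languages)
        if item.codelist_oid:
            etree.SubElement(idef, _Q + "CodeListRef",
                             CodeListOID=item.codelist_oid)
        _aliases(idef, item.codes)
    for cl in model.codelists:
        cle = etree.SubElement(mdv, _Q + "CodeList", OID=cl.oid, Name=cl.oid,
                               DataType=cl.datatype)
        for cli in cl.items:
            clie = etree.SubElement(cle, _Q + "CodeListItem",
                                    CodedValue=cli.coded_value)
            _translated(clie, "Decode", cli.decodes, model.languages)
            _aliases(clie, cli.codes)
    if h.contact_first_name or h.contact_last_name or h.contact_organization:
        admin = etree.SubElement(root, _Q + "AdminData")
        user = etree.SubElement(admin, _Q + "User", OID="USR.1")
        etree.SubElement(user, _Q + "FirstName").text = h.contact_first_name
        etree.SubElement(user, _Q + "LastName").text = h.contact_last_name
        etree.SubElement(user, _Q + "Organization").text = h.contact_organization
    text = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True).decode("utf-8")
    return OdmDocument(text)


def _read_translated(parent: etree._Element, tag: str,
                     languages: list[str]) -> dict[str, str]:
    out: dict[str, str] = {}
    el = parent.find(_Q + tag)
    if el is None:
        return out
    for tt in el.findall(_Q + "TranslatedText"):
        lang = tt.get(XML_LANG, "en")
        out[lang] = tt.text or ""
        if lang not in languages:
            languages.append(lang)
    return out


def _read_aliases(parent: etree._Element) -> list[SemanticCode]:
    return [SemanticCode(a.get("Context", ""), a.get("Name", ""))
            for a in parent.findall(_Q + "Alias")]


def _map_datatype(raw: str, oid: str) -> str:
    if raw in DATATYPES:
        return raw
    mapped = FOREIGN_DATATYPES.get(raw)
    if mapped is None:
        mapped = "string"
    log.warning("item %s: unsupported DataType %r mapped to %r", oid, raw, mapped)
    return mapped


def _split_description(text: str) -> tuple[str, str, str]:
    """Invert the Sponsor/Condition prefix convention on StudyDescription."""
    sponsor = condition = ""
    lines = text.split("\n")
    if lines and lines[0].startswith("Sponsor: "):
        sponsor = lines.pop(0)[len("Sponsor: "):]
        if lines and lines[0].startswith("Condition: "):
            condition = lines.pop(0)[len("Condition: "):]
    return sponsor, condition, "\n".join(lines)


def read_odm(document: OdmDocument) -> StudyModel:
    """Parse an ODM 1.3 metadata document into a study model.

    Inverse of :func:`write_odm` on documents this package wrote.  Foreign
    documents are accepted leniently; recoverable oddities are logged as
    warnings, structural defects raise :class:`OdmFormatError`.
    """
    root = document.root()
    if etree.QName(root).namespace != ODM_NS or etree.QName(root).localname != "ODM":
        raise OdmFormatError(
            f"root element is {root.tag!r}, expected ODM in namespace {ODM_NS}")
    study = root.find(_Q + "Study")
    if study is None:
        raise OdmFormatError("document contains no Study element")
    header = StudyHeader(study_oid=study.get("OID", "S.0000"))
    gv = study.find(_Q + "GlobalVariables")
    if gv is not None:
        header.study_name = gv.findtext(_Q + "StudyName", default="") or ""
        raw_desc = gv.findtext(_Q + "StudyDescription", default="") or ""
        (header.sponsor, header.condition,
         header.study_description) = _split_description(raw_desc)
        header.form_name = gv.findtext(_Q + "ProtocolName", default="") or ""
    admin_user = root.find(f"{_Q}AdminData/{_Q}User")
    if admin_user is not None:
        header.contact_first_name = admin_user.findtext(_Q + "FirstName", default="") or ""
        header.contact_last_name = admin_user.findtext(_Q + "LastName", default="") or ""
        header.contact_organization = admin_user.findtext(_Q + "Organization", default="") or ""

    mdv = study.find(_Q + "MetaDataVersion")
    if mdv is None:
        raise OdmFormatError("Study has no MetaDataVersion")
    for tag in _IGNORED_METADATA:
        if mdv.find(_Q + tag) is not None:
            log.warning("ignoring %s metadata (outside the form model)", tag)

    forms = mdv.findall(_Q + "FormDef")
    languages: list[str] = []
    model = StudyModel(header=header, languages=languages)
    if not forms:
        return canonicalize(model)
    if len(forms) > 1:
        log.warning("document defines %d forms; parsing the first only", len(forms))
    form = forms[0]
    model.form_oid = form.get("OID", "F.1")
    if form.get("Name"):
        header.form_name = form.get("Name", header.form_name)

    igdefs = {g.get("OID"): g for g in mdv.findall(_Q + "ItemGroupDef")}
    idefs = {i.get("OID"): i for i in mdv.findall(_Q + "ItemDef")}
    cldefs = {c.get("OID"): c for c in mdv.findall(_Q + "CodeList")}

    for gref in form.findall(_Q + "ItemGroupRef"):
        goid = gref.get("ItemGroupOID", "")
        gdef = igdefs.get(goid)
        if gdef is None:
            log.warning("ItemGroupRef %s has no ItemGroupDef; skipped", goid)
            continue
        group = ItemGroup(oid=goid, name=gdef.get("Name", goid),
                          labels=_read_translated(gdef, "Description", languages),
                          codes=_read_aliases(gdef))
        model.groups.append(group)
        for iref in gdef.findall(_Q + "ItemRef"):
            ioid = iref.get("ItemOID", "")
            idef = idefs.get(ioid)
            if idef is None:
                log.warning("ItemRef %s has no ItemDef; skipped", ioid)
                continue
            item = Item(oid=ioid, name=idef.get("Name", ioid),
                        datatype=_map_datatype(idef.get("DataType", "string"), ioid),
                        labels=_read_translated(idef, "Question", languages),
                        codes=_read_aliases(idef))
            clref = idef.find(_Q + "CodeListRef")
            if clref is not None:
                cloid = clref.get("CodeListOID", "")
                cldef = cldefs.get(cloid)
                if cldef is None:
                    log.warning("CodeListRef %s has no CodeList; dropped", cloid)
                else:
                    item.codelist_oid = cloid
                    if model.codelist(cloid) is None:
                        cl = CodeList(oid=cloid,
                                      datatype=cldef.get("DataType", "string"))
                        for clie in cldef.findall(_Q + "CodeListItem"):
                            cl.items.append(CodeListItem(
                                coded_value=clie.get("CodedValue", ""),
                                decodes=_read_translated(clie, "Decode", languages),
                                codes=_read_aliases(clie)))
                        model.codelists.append(cl)
            group.items.append(item)
    return canonicalize(model)


def validate_against_schema(document: OdmDocument, schema_path: str | Path) -> list[str]:
    """Validate against a locally provided ODM 1.3 XSD; returns messages.

    The schema is not bundled (CDISC distributes it under its own terms);
    callers that have it pass its path.
    """
    schema = etree.XMLSchema(etree.parse(str(schema_path)))
    tree = etree.fromstring(document.xml_text.encode("utf-8"))
    if schema.validate(tree):
        return []
    return [str(e) for e in schema.error_log]
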