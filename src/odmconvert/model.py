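"""Canonical in-memory representation of a clinical study data model.

A case report form (CRF) is modelled as a single form holding ordered item
groups, each group holding ordered data items.  Items may reference a code
list of permissible values.  Every level — item group, item and permissible
value — may carry semantic annotations: (terminology designation, code
value) pairs from healthcare terminologies such as UMLS, SNOMED CT or
LOINC.  All converters in this package read and write this one structure,
so round-trip guarantees are stated against it.

Model equality for round-trip checks is field-by-field equality after
:func:`canonicalize`; byte equality of serialized files is deliberately not
required (XML and CSV writers may differ in whitespace).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

#: The six item datatypes supported by every representation.
DATATYPES = ("boolean", "integer", "date", "float", "string", "time")

#: Datatypes that may carry a code list of permissible values.
CODED_DATATYPES = ("integer", "string")


class ModelError(ValueError):
    """Raised when an operation receives a structurally unusable model."""


@dataclass(frozen=True, order=True)
class SemanticCode:
    """One semantic annotation: a terminology designation plus a code value.

    The terminology designation is kept exactly as given in the source
    (e.g. ``"SNOMED CT 2010_0731"``, ``"UMLS CUI"``, ``"LOINC"``); it is an
    opaque label, version suffixes included.
    """

    terminology: str
    code: str


@dataclass
class CodeListItem:
    """One permissible value: stored code, display decodes, annotations."""

    coded_value: str
    decodes: dict[str, str] = field(default_factory=dict)  # language -> text
    codes: list[SemanticCode] = field(default_factory=list)


@dataclass
class CodeList:
    oid: str
    datatype: str  # "integer" or "string"
    items: list[CodeListItem] = field(default_factory=list)


@dataclass
class Item:
    """A single data item (one CRF question / one dataset variable)."""

    oid: str
    name: str
    datatype: str
    labels: dict[str, str] = field(default_factory=dict)  # language -> question text
    codes: list[SemanticCode] = field(default_factory=list)
    codelist_oid: str | None = None


@dataclass
class ItemGroup:
    oid: str
    name: str
    labels: dict[str, str] = field(default_factory=dict)
    codes: list[SemanticCode] = field(default_factory=list)
    items: list[Item] = field(default_factory=list)


@dataclass
class StudyHeader:
    """Administrative study information (the office template header block)."""

    study_oid: str = "S.0000"
    sponsor: str = ""
    condition: str = ""
    study_name: str = ""
    study_description: str = ""
    form_name: str = "Form"
    contact_first_name: str = ""
    contact_last_name: str = ""
    contact_organization: str = ""


@dataclass
class StudyModel:
    """One study's form: header, ordered groups, code lists, languages."""

    header: StudyHeader = field(default_factory=StudyHeader)
    groups: list[ItemGroup] = field(default_factory=list)
    codelists: list[CodeList] = field(default_factory=list)
    languages: list[str] = field(default_factory=list)
    form_oid: str = "F.1"

    def items(self) -> Iterator[Item]:
        """All items in document order."""
        for group in self.groups:
            yield from group.items

    def codelist(self, oid: str) -> CodeList | None:
        for cl in self.codelists:
            if cl.oid == oid:
                return cl
        return None


@dataclass
class Violation:
    severity: str  # "error" | "warning"
    location: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def errors(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "error"]

    @property
    def ok(self) -> bool:
        return not self.violations


def _check_codes(codes: list[SemanticCode], location: str, out: list[Violation]) -> None:
    for sc in codes:
        if not sc.terminology.strip():
            out.append(Violation("error", location, "semantic code with empty terminology"))
        if not sc.code or sc.code != sc.code.strip():
            out.append(Violation(
                "error", location,
                f"semantic code value {sc.code!r} empty or carries surrounding whitespace"))


def validate_model(model: StudyModel) -> ValidationReport:
    """Check every structural invariant; never raises, reports instead."""
    v: list[Violation] = []
    if not model.header.study_oid.strip():
        v.append(Violation("error", "header", "StudyOID is empty"))
    if not model.header.form_name.strip():
        v.append(Violation("error", "header", "Form name is empty"))

    seen_oids: dict[str, str] = {}

    def register(oid: str, what: str) -> None:
        if oid in seen_oids:
            v.append(Violation("error", f"{what} {oid}",
                               f"OID {oid!r} already used by {seen_oids[oid]}"))
        else:
            seen_oids[oid] = what

    referenced: set[str] = set()
    for group in model.groups:
        loc = f"itemgroup {group.name or group.oid}"
        register(group.oid, "itemgroup")
        _check_codes(group.codes, loc, v)
        for item in group.items:
            iloc = f"item {item.name or item.oid}"
            register(item.oid, "item")
            if item.datatype not in DATATYPES:
                v.append(Violation("error", iloc, f"unknown datatype {item.datatype!r}"))
            _check_codes(item.codes, iloc, v)
            if item.codelist_oid is not None:
                referenced.add(item.codelist_oid)
                cl = model.codelist(item.codelist_oid)
                if cl is None:
                    v.append(Violation("error", iloc,
                                       f"references code list {item.codelist_oid!r}"
                                       " which is not defined"))
                elif cl.datatype != item.datatype:
                    v.append(Violation("error", iloc,
                                       f"code list datatype {cl.datatype!r} differs from"
                                       f" item datatype {item.datatype!r}"))

    for cl in model.codelists:
        loc = f"codelist {cl.oid}"
        register(cl.oid, "codelist")
        if cl.datatype not in CODED_DATATYPES:
            v.append(Violation("error", loc,
                               f"code list datatype must be integer or string,"
                               f" got {cl.datatype!r}"))
        if cl.oid not in referenced:
            v.append(Violation("warning", loc, "code list is not referenced by any item"))
        seen_values: set[str] = set()
        for cli in cl.items:
            if not cli.coded_value:
                v.append(Violation("error", loc, "empty coded value"))
            if cli.coded_value in seen_values:
                v.append(Violation("error", loc,
                                   f"duplicate coded value {cli.coded_value!r}"))
            seen_values.add(cli.coded_value)
            if not cli.decodes:
                v.append(Violation("error", f"{loc} value {cli.coded_value!r}",
                                   "permissible value has no decode text"))
            _check_codes(cli.codes, f"{loc} value {cli.coded_value!r}", v)
    return ValidationReport(v)


def assign_oids(model: StudyModel) -> StudyModel:
    """Assign deterministic OIDs in document order.

    Items become ``I.001``, ``I.002``, … (zero-padded to at least three
    digits, widening when a model has more than 999 items); groups become
    ``IG.1``, ``IG.2``, …; each code list is named after its owning item
    (``CL.I.001``); the form is ``F.1``.  The study OID is kept.  The
    operation is deterministic and idempotent.
    """
    n_items = sum(len(g.items) for g in model.groups)
    width = max(3, len(str(n_items)))
    new_groups: list[ItemGroup] = []
    new_codelists: list[CodeList] = []
    counter = 0
    for gi, group in enumerate(model.groups, start=1):
        new_items: list[Item] = []
        for item in group.items:
            counter += 1
            oid = f"I.{counter:0{width}d}"
            cl_oid = None
            if item.codelist_oid is not None:
                cl = model.codelist(item.codelist_oid)
                if cl is not None:
                    cl_oid = f"CL.{oid}"
                    new_codelists.append(replace(cl, oid=cl_oid))
            new_items.append(replace(item, oid=oid, codelist_oid=cl_oid))
        new_groups.append(replace(group, oid=f"IG.{gi}", items=new_items))
    return replace(model, groups=new_groups, codelists=new_codelists, form_oid="F.1")


def _strip_labels(labels: dict[str, str]) -> dict[str, str]:
    return {lang.strip(): text.strip() for lang, text in labels.items()}


def _canon_codes(codes: list[SemanticCode]) -> list[SemanticCode]:
    return sorted({SemanticCode(c.terminology.strip(), c.code.strip()) for c in codes})


def canonicalize(model: StudyModel) -> StudyModel:
    """Normalize a model so field-by-field equality means semantic equality.

    Trims surrounding whitespace in every text field, drops code lists no
    item references, sorts each annotation collection by (terminology,
    code), and prunes declared languages that never occur in a label or
    decode.  Item, group and permissible-value order is untouched.
    Idempotent.
    """
    h = model.header
    header = StudyHeader(*(getattr(h, f.name).strip() for f in
                           h.__dataclass_fields__.values()))
    used_langs: set[str] = set()
    groups: list[ItemGroup] = []
    referenced: set[str] = set()
    for group in model.groups:
        items: list[Item] = []
        for item in group.items:
            labels = _strip_labels(item.labels)
            used_langs.update(labels)
            if item.codelist_oid is not None:
                referenced.add(item.codelist_oid)
            items.append(Item(
                oid=item.oid.strip(), name=item.name.strip(),
                datatype=item.datatype.strip(), labels=labels,
                codes=_canon_codes(item.codes),
                codelist_oid=item.codelist_oid.strip() if item.codelist_oid else None))
        labels = _strip_labels(group.labels)
        used_langs.update(labels)
        groups.append(ItemGroup(
            oid=group.oid.strip(), name=group.name.strip(), labels=labels,
            codes=_canon_codes(group.codes), items=items))
    codelists: list[CodeList] = []
    for cl in model.codelists:
        if cl.oid not in referenced:
            continue  # orphan: unreachable from any item
        entries = []
        for cli in cl.items:
            decodes = _strip_labels(cli.decodes)
            used_langs.update(decodes)
            entries.append(CodeListItem(cli.coded_value.strip(), decodes,
                                        _canon_codes(cli.codes)))
        codelists.append(CodeList(cl.oid.strip(), cl.datatype.strip(), entries))
    languages = [lang.strip() for lang in model.languages if lang.strip() in used_langs]
    return StudyModel(header=header, groups=groups, codelists=codelists,
                      languages=languages, form_oid=model.form_oid.strip())


def iter_codes(model: StudyModel) -> Iterator[tuple[str, SemanticCode]]:
    """Yield every semantic annotation with a human-readable location."""
    for group in model.groups:
        for sc in group.codes:
            yield f"itemgroup {group.name}", sc
        for item in group.items:
            for sc in item.codes:
                yield f"item {item.name}", sc
            if item.codelist_oid:
                cl = model.codelist(item.codelist_oid)
                if cl is None:
                    continue
                for cli in cl.items:
                    for sc in cli.codes:
                        yield f"item {item.name} value {cli.coded_value}", sc


def count_codes(model: StudyModel) -> int:
    """Total number of semantic annotations at all three levels."""
    return sum(1 for _ in iter_codes(model))
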