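"""Labelled statistics dataset: the statistician's view of the model.

The study model becomes a zero-row (metadata-only) table with one column
per item, named by the item OID (``I.001`` …).  Variable labels, value
labels, per-variable and per-value semantic codes, group membership and
study-level attributes travel alongside the table, so the model can be
reconstructed losslessly (``from_stats(to_stats(m)) == canonicalize(m)``).

On disk the dataset is a CSV data table plus a JSON metadata sidecar —
language-neutral, diffable and lossless.  Native labelled formats of
statistics ecosystems (SPSS/SAS transport) are deliberately not the
round-trip carrier.  When subject data exist in an ODM document's
``ClinicalData`` section, :func:`attach_clinical_data` appends one row per
subject.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .model import (
    CODED_DATATYPES, CodeList, CodeListItem, Item, ItemGroup, SemanticCode,
    StudyHeader, StudyModel, canonicalize,
)
from .odm import ODM_NS, OdmDocument

log = logging.getLogger(__name__)

#: item datatype -> column storage class
STORAGE = {"boolean": "logical", "integer": "integer", "float": "real",
           "date": "text", "time": "text", "string": "text"}
_STORAGE_DEFAULT_DATATYPE = {"logical": "boolean", "integer": "integer",
                             "real": "float", "text": "string"}

_ATTR_FIELDS = (("StudyOID", "study_oid"), ("StudyName", "study_name"),
                ("StudyDescription", "study_description"),
                ("Sponsor", "sponsor"), ("Condition", "condition"),
                ("Form", "form_name"), ("FirstName", "contact_first_name"),
                ("LastName", "contact_last_name"),
                ("Organization", "contact_organization"))


class StatsFormatError(ValueError):
    """The dataset violates the labelled-dataset metadata contract."""


@dataclass
class Column:
    column_id: str  # item OID
    storage_type: str  # logical | integer | real | text
    values: list = field(default_factory=list)


@dataclass
class GroupMeta:
    name: str
    labels: dict[str, str] = field(default_factory=dict)
    codes: list[SemanticCode] = field(default_factory=list)


@dataclass
class LabelledDataset:
    """A typed table plus everything needed to rebuild the study model.

    ``variable_labels`` / ``value_labels`` hold the single chosen language
    (what a statistics package displays); the ``*_i18n`` mappings retain
    every language so the inverse conversion loses nothing.
    """

    columns: list[Column] = field(default_factory=list)
    language: str = "en"
    languages: list[str] = field(default_factory=list)
    variable_labels: dict[str, str] = field(default_factory=dict)
    value_labels: dict[str, dict[str, str]] = field(default_factory=dict)
    variable_codes: dict[str, list[SemanticCode]] = field(default_factory=dict)
    group_of: dict[str, str] = field(default_factory=dict)
    group_meta: dict[str, GroupMeta] = field(default_factory=dict)
    study_attributes: dict[str, str] = field(default_factory=dict)
    # lossless extras
    variable_names: dict[str, str] = field(default_factory=dict)
    variable_labels_i18n: dict[str, dict[str, str]] = field(default_factory=dict)
    value_decodes_i18n: dict[str, dict[str, dict[str, str]]] = field(default_factory=dict)
    value_codes: dict[str, dict[str, list[SemanticCode]]] = field(default_factory=dict)
    original_datatypes: dict[str, str] = field(default_factory=dict)
    codelist_oids: dict[str, str] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.columns[0].values) if self.columns else 0

    def column(self, column_id: str) -> Column:
        for col in self.columns:
            if col.column_id == column_id:
                return col
        raise KeyError(column_id)


def to_stats(model: StudyModel, language: str | None = None) -> LabelledDataset:
    """Project a study model onto a labelled, zero-row dataset.

    One column per item in document order; ``language`` selects which label
    language the primary (display) mappings use and defaults to the model's
    first language.
    """
    model = canonicalize(model)
    if language is None:
        language = model.languages[0] if model.languages else "en"
    elif model.languages and language not in model.languages:
        raise StatsFormatError(f"language {language!r} not present in model "
                               f"(has {model.languages})")
    ds = LabelledDataset(language=language, languages=list(model.languages))
    ds.study_attributes = {key: getattr(model.header, attr)
                           for key, attr in _ATTR_FIELDS}
    for group in model.groups:
        ds.group_meta[group.oid] = GroupMeta(group.name, dict(group.labels),
                                             list(group.codes))
        for item in group.items:
            cid = item.oid
            ds.columns.append(Column(cid, STORAGE[item.datatype]))
            ds.variable_names[cid] = item.name
            ds.variable_labels[cid] = item.labels.get(language, item.name)
            ds.variable_labels_i18n[cid] = dict(item.labels)
            ds.variable_codes[cid] = list(item.codes)
            ds.group_of[cid] = group.oid
            ds.original_datatypes[cid] = item.datatype
            if item.codelist_oid:
                cl = model.codelist(item.codelist_oid)
                if cl is not None:
                    ds.codelist_oids[cid] = cl.oid
                    ds.value_labels[cid] = {
                        e.coded_value: e.decodes.get(language,
                                                     next(iter(e.decodes.values()), ""))
                        for e in cl.items}
                    ds.value_decodes_i18n[cid] = {
                        e.coded_value: dict(e.decodes) for e in cl.items}
                    ds.value_codes[cid] = {
                        e.coded_value: list(e.codes) for e in cl.items}
    return ds


def from_stats(ds: LabelledDataset) -> StudyModel:
    """Rebuild the study model from a labelled dataset.

    Inverse of :func:`to_stats`.  Columns without a recorded group land in
    a synthesized group ``IG.1``/``Ungrouped``; columns without a recorded
    source datatype fall back to the storage-class default.
    """
    seen: set[str] = set()
    for col in ds.columns:
        if col.column_id in seen:
            raise StatsFormatError(f"duplicate column id {col.column_id!r}")
        seen.add(col.column_id)
    for mapping, what in ((ds.value_labels, "value_labels"),
                          (ds.variable_codes, "variable_codes")):
        for cid in mapping:
            if cid not in seen:
                raise StatsFormatError(f"{what} keyed to missing column {cid!r}")

    header = StudyHeader(**{attr: ds.study_attributes.get(key, "")
                            for key, attr in _ATTR_FIELDS})
    if not header.study_oid:
        header.study_oid = "S.0000"
    if not header.form_name:
        header.form_name = "Form"
    model = StudyModel(header=header, languages=list(ds.languages) or [ds.language])
    groups: dict[str, ItemGroup] = {}
    for col in ds.columns:
        cid = col.column_id
        goid = ds.group_of.get(cid, "IG.1")
        if goid not in groups:
            meta = ds.group_meta.get(goid, GroupMeta("Ungrouped"))
            groups[goid] = ItemGroup(oid=goid, name=meta.name,
                                     labels=dict(meta.labels),
                                     codes=list(meta.codes))
            model.groups.append(groups[goid])
        datatype = ds.original_datatypes.get(
            cid, _STORAGE_DEFAULT_DATATYPE.get(col.storage_type, "string"))
        labels = dict(ds.variable_labels_i18n.get(cid, {}))
        if not labels and cid in ds.variable_labels:
            name = ds.variable_names.get(cid, cid)
            if ds.variable_labels[cid] != name:  # label fell back to the name
                labels = {ds.language: ds.variable_labels[cid]}
        item = Item(oid=cid, name=ds.variable_names.get(cid, cid),
                    datatype=datatype, labels=labels,
                    codes=list(ds.variable_codes.get(cid, [])))
        if cid in ds.value_labels:
            if datatype not in CODED_DATATYPES:
                raise StatsFormatError(
                    f"column {cid!r}: value labels on {datatype!r} variable")
            cl = CodeList(oid=ds.codelist_oids.get(cid, f"CL.{cid}"),
                          datatype=datatype)
            decodes_i18n = ds.value_decodes_i18n.get(cid, {})
            codes_by_value = ds.value_codes.get(cid, {})
            for coded, decode in ds.value_labels[cid].items():
                decodes = dict(decodes_i18n.get(coded, {})) or {ds.language: decode}
                cl.items.append(CodeListItem(coded, decodes,
                                             list(codes_by_value.get(coded, []))))
            item.codelist_oid = cl.oid
            model.codelists.append(cl)
        groups[goid].items.append(item)
    return canonicalize(model)


# ---------------------------------------------------------------------------
# clinical data rows

_Q = "{%s}" % ODM_NS

_MISSING = (None, "")


def _coerce(value: str, storage: str, subject: str, oid: str):
    if storage == "integer":
        try:
            return int(value)
        except ValueError:
            raise StatsFormatError(
                f"subject {subject}, item {oid}: {value!r} is not an integer")
    if storage == "real":
        try:
            return float(value)
        except ValueError:
            raise StatsFormatError(
                f"subject {subject}, item {oid}: {value!r} is not a number")
    if storage == "logical":
        lowered = value.strip().lower()
        if lowered in ("true", "1", "yes"):
            return True
        if lowered in ("false", "0", "no"):
            return False
        raise StatsFormatError(
            f"subject {subject}, item {oid}: {value!r} is not a boolean")
    return value  # text: dates/times stay ISO-8601 strings


def attach_clinical_data(ds: LabelledDataset, document: OdmDocument) -> LabelledDataset:
    """Append one row per subject from the document's ClinicalData section.

    Cells are taken from ``ItemData/@Value`` keyed by item OID, typed
    according to the column storage class; items a subject did not answer
    become missing values.  Values for unknown item OIDs are dropped with
    a warning.  The input dataset is not modified.
    """
    import copy

    out = copy.deepcopy(ds)
    known = {col.column_id: col for col in out.columns}
    root = document.root()
    for cdata in root.findall(_Q + "ClinicalData"):
        for subject in cdata.findall(_Q + "SubjectData"):
            skey = subject.get("SubjectKey", "?")
            row: dict[str, object] = {}
            for idata in subject.iter(_Q + "ItemData"):
                oid = idata.get("ItemOID", "")
                value = idata.get("Value")
                if oid not in known:
                    log.warning("subject %s: value for unknown item %s dropped",
                                skey, oid)
                    continue
                if value in _MISSING:
                    row[oid] = None
                else:
                    row[oid] = _coerce(value, known[oid].storage_type, skey, oid)
            for col in out.columns:
                col.values.append(row.get(col.column_id))
    return out


# ---------------------------------------------------------------------------
# on-disk form: CSV table + JSON sidecar

def _codes_json(codes: list[SemanticCode]) -> list[dict[str, str]]:
    return [{"terminology": c.terminology, "code": c.code} for c in codes]


def _codes_from_json(raw: list[dict[str, str]]) -> list[SemanticCode]:
    return [SemanticCode(c["terminology"], c["code"]) for c in raw]


def save_stats(ds: LabelledDataset, path: str | Path) -> tuple[Path, Path]:
    """Write ``<path>.csv`` (data) and ``<path>.meta.json`` (sidecar)."""
    base = Path(path)
    if base.suffix == ".csv":
        base = base.with_suffix("")
    csv_path = base.with_suffix(".csv")
    meta_path = base.parent / (base.name + ".meta.json")
    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([c.column_id for c in ds.columns])
        for r in range(ds.n_rows):
            writer.writerow(["" if c.values[r] is None else
                             ("TRUE" if c.values[r] is True else
                              "FALSE" if c.values[r] is False else str(c.values[r]))
                             for c in ds.columns])
    meta = {
        "format": "odmconvert-labelled-dataset",
        "version": 1,
        "language": ds.language,
        "languages": ds.languages,
        "n_rows": ds.n_rows,
        "study_attributes": ds.study_attributes,
        "groups": {goid: {"name": g.name, "labels": g.labels,
                          "codes": _codes_json(g.codes)}
                   for goid, g in ds.group_meta.items()},
        "variables": [
            {
                "oid": col.column_id,
                "storage": col.storage_type,
                "datatype": ds.original_datatypes.get(col.column_id),
                "name": ds.variable_names.get(col.column_id, col.column_id),
                "label": ds.variable_labels.get(col.column_id, ""),
                "labels": ds.variable_labels_i18n.get(col.column_id, {}),
                "codes": _codes_json(ds.variable_codes.get(col.column_id, [])),
                "group": ds.group_of.get(col.column_id),
                "codelist_oid": ds.codelist_oids.get(col.column_id),
                "value_labels": ds.value_labels.get(col.column_id),
                "value_decodes": ds.value_decodes_i18n.get(col.column_id),
                "value_codes": {coded: _codes_json(codes) for coded, codes in
                                ds.value_codes.get(col.column_id, {}).items()} or None,
            }
            for col in ds.columns
        ],
    }
    meta_path.write_text(json.dumps(meta, indent=2, ensure_ascii=False) + "\n",
                         encoding="utf-8")
    return csv_path, meta_path


def _parse_cell(text: str, storage: str):
    if text == "":
        return None
    if storage == "integer":
        return int(text)
    if storage == "real":
        return float(text)
    if storage == "logical":
        return text.strip().upper() == "TRUE"
    return text


def load_stats(path: str | Path) -> LabelledDataset:
    """Read a dataset written by :func:`save_stats`."""
    base = Path(path)
    if base.suffix == ".csv":
        base = base.with_suffix("")
    elif base.name.endswith(".meta.json"):
        base = base.parent / base.name[:-len(".meta.json")]
    csv_path = base.with_suffix(".csv")
    meta_path = base.parent / (base.name + ".meta.json")
    try:
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise StatsFormatError(f"cannot read sidecar {meta_path}: {exc}") from exc
    if meta.get("format") != "odmconvert-labelled-dataset":
        raise StatsFormatError(f"{meta_path} is not a labelled-dataset sidecar")

    ds = LabelledDataset(language=meta.get("language", "en"),
                         languages=list(meta.get("languages", [])),
                         study_attributes=dict(meta.get("study_attributes", {})))
    for goid, g in meta.get("groups", {}).items():
        ds.group_meta[goid] = GroupMeta(g.get("name", goid),
                                        dict(g.get("labels", {})),
                                        _codes_from_json(g.get("codes", [])))
    for var in meta.get("variables", []):
        cid = var["oid"]
        ds.columns.append(Column(cid, var.get("storage", "text")))
        ds.variable_names[cid] = var.get("name", cid)
        ds.variable_labels[cid] = var.get("label", "")
        ds.variable_labels_i18n[cid] = dict(var.get("labels", {}))
        ds.variable_codes[cid] = _codes_from_json(var.get("codes", []))
        if var.get("group") is not None:
            ds.group_of[cid] = var["group"]
        if var.get("datatype"):
            ds.original_datatypes[cid] = var["datatype"]
        if var.get("codelist_oid"):
            ds.codelist_oids[cid] = var["codelist_oid"]
        if var.get("value_labels") is not None:
            ds.value_labels[cid] = dict(var["value_labels"])
        if var.get("value_decodes") is not None:
            ds.value_decodes_i18n[cid] = {coded: dict(d) for coded, d in
                                          var["value_decodes"].items()}
        if var.get("value_codes") is not None:
            ds.value_codes[cid] = {coded: _codes_from_json(codes) for coded, codes
                                   in var["value_codes"].items()}
    with open(csv_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is not None:
            order = {cid: i for i, cid in enumerate(header)}
            for row in reader:
                for col in ds.columns:
                    i = order.get(col.column_id)
                    text = row[i] if i is not None and i < len(row) else ""
                    col.values.append(_parse_cell(text, col.storage_type))
    return ds
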