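"""Office spreadsheet template: the study-model dialect PIs edit by hand.

The template is a plain cell grid.  Lines 1–9 hold header key/value pairs
(``StudyOID``, ``Sponsor``, ``Condition``, ``StudyName``,
``StudyDescription``, ``Form``, ``FirstName``, ``LastName``,
``Organization``), line 10 is blank, line 11 is the column header
(``Type``, ``Name``, one column per language tag, one column per
terminology designation), and every following line describes an item
group, a data item (keyed by its datatype in column A) or a permissible
value (``codelistitem``).  One annotation cell holds at most one code; the
column header is the terminology designation.

The grid travels as CSV (RFC 4180, UTF-8) or as the first worksheet of an
XLSX workbook.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

from .model import (
    CODED_DATATYPES, DATATYPES, CodeList, CodeListItem, Item, ItemGroup,
    SemanticCode, StudyHeader, StudyModel, assign_oids, canonicalize,
)

HEADER_KEYS = ("StudyOID", "Sponsor", "Condition", "StudyName",
               "StudyDescription", "Form", "FirstName", "LastName",
               "Organization")

_HEADER_FIELDS = dict(zip(HEADER_KEYS, (
    "study_oid", "sponsor", "condition", "study_name", "study_description",
    "form_name", "contact_first_name", "contact_last_name",
    "contact_organization")))

# language columns are short lowercase BCP-47 primary tags; the first header
# cell that is not one starts the open-ended terminology columns
_LANG_RE = re.compile(r"^[a-z]{2,3}$")


class OfficeFormatError(ValueError):
    """The grid does not follow the template dialect."""


@dataclass
class CellGrid:
    """Rectangular-ish grid of text cells; short rows are padded on read."""

    rows: list[list[str]] = field(default_factory=list)
    origin: str = "csv"

    def cell(self, r: int, c: int) -> str:
        row = self.rows[r] if r < len(self.rows) else []
        return row[c] if c < len(row) else ""


def _is_blank(row: list[str]) -> bool:
    return all(not cell.strip() for cell in row)


def read_office(grid: CellGrid) -> StudyModel:
    """Parse the office template grid into a study model.

    Header keys are matched by label, not by row position, so hand-reordered
    headers still parse.  Returns a model with freshly assigned OIDs.
    """
    if len(grid.rows) < 11:
        raise OfficeFormatError(
            f"template needs at least 11 rows, got {len(grid.rows)}")

    # locate the column-header row: first row whose column A is "Type"
    col_header_idx = None
    header = StudyHeader(study_oid="", form_name="")
    seen_keys: set[str] = set()
    for idx, row in enumerate(grid.rows):
        key = row[0].strip() if row else ""
        if key == "Type":
            col_header_idx = idx
            break
        if not key:
            continue
        if key not in _HEADER_FIELDS:
            raise OfficeFormatError(f"row {idx + 1}: unknown header key {key!r}")
        setattr(header, _HEADER_FIELDS[key], grid.cell(idx, 1).strip())
        seen_keys.add(key)
    if col_header_idx is None:
        raise OfficeFormatError('column header row starting with "Type" not found')
    for key in ("StudyOID", "Form"):
        if key not in seen_keys:
            raise OfficeFormatError(f"missing header key {key!r}")

    head_row = grid.rows[col_header_idx]
    if len(head_row) < 2 or head_row[1].strip() != "Name":
        raise OfficeFormatError(
            f'row {col_header_idx + 1}: column header must read "Type","Name",…')
    languages: list[str] = []
    terminologies: list[tuple[int, str]] = []  # (column index, designation)
    for col in range(2, len(head_row)):
        text = head_row[col].strip()
        if not text:
            continue
        if not terminologies and _LANG_RE.match(text):
            languages.append(text)
        else:
            terminologies.append((col, text))
    lang_cols = list(range(2, 2 + len(languages)))

    model = StudyModel(header=header, languages=languages)
    group: ItemGroup | None = None
    item: Item | None = None

    def cell_codes(row_idx: int) -> list[SemanticCode]:
        out = []
        for col, designation in terminologies:
            value = grid.cell(row_idx, col).strip()
            if value:
                out.append(SemanticCode(designation, value))
        return out

    def cell_labels(row_idx: int) -> dict[str, str]:
        out = {}
        for lang, col in zip(languages, lang_cols):
            value = grid.cell(row_idx, col).strip()
            if value:
                out[lang] = value
        return out

    for idx in range(col_header_idx + 1, len(grid.rows)):
        row = grid.rows[idx]
        if _is_blank(row):
            continue
        token = grid.cell(idx, 0).strip()
        name = grid.cell(idx, 1).strip()
        if token == "itemgroup":
            group = ItemGroup(oid="", name=name, labels=cell_labels(idx),
                              codes=cell_codes(idx))
            model.groups.append(group)
            item = None
        elif token == "codelistitem":
            if item is None:
                raise OfficeFormatError(
                    f"row {idx + 1}: codelistitem before any data item")
            if item.datatype not in CODED_DATATYPES:
                raise OfficeFormatError(
                    f"row {idx + 1}: code list attached to {item.datatype!r} item"
                    f" {item.name!r}; only integer and string items take code lists")
            if item.codelist_oid is None:
                item.codelist_oid = f"CL.tmp{len(model.codelists)}"
                model.codelists.append(
                    CodeList(oid=item.codelist_oid, datatype=item.datatype))
            cl = model.codelist(item.codelist_oid)
            assert cl is not None
            cl.items.append(CodeListItem(coded_value=name,
                                         decodes=cell_labels(idx),
                                         codes=cell_codes(idx)))
        elif token in DATATYPES:
            if group is None:
                group = ItemGroup(oid="", name="Ungrouped")
                model.groups.append(group)
            item = Item(oid="", name=name, datatype=token,
                        labels=cell_labels(idx), codes=cell_codes(idx))
            group.items.append(item)
        else:
            raise OfficeFormatError(f"row {idx + 1}: unknown Type token {token!r}")
    return canonicalize(assign_oids(model))


def write_office(model: StudyModel) -> CellGrid:
    """Serialize a model into the template grid ``read_office`` consumes.

    Terminology columns appear in first-occurrence order over the document;
    every semantic annotation lands in exactly one cell.
    """
    terminologies: list[str] = []

    def note(codes: list[SemanticCode]) -> None:
        for sc in codes:
            if sc.terminology not in terminologies:
                terminologies.append(sc.terminology)

    for group in model.groups:
        note(group.codes)
        for it in group.items:
            note(it.codes)
            if it.codelist_oid:
                cl = model.codelist(it.codelist_oid)
                if cl:
                    for cli in cl.items:
                        note(cli.codes)

    h = model.header
    rows: list[list[str]] = [
        ["StudyOID", h.study_oid], ["Sponsor", h.sponsor],
        ["Condition", h.condition], ["StudyName", h.study_name],
        ["StudyDescription", h.study_description], ["Form", h.form_name],
        ["FirstName", h.contact_first_name], ["LastName", h.contact_last_name],
        ["Organization", h.contact_organization],
        [],
        ["Type", "Name", *model.languages, *terminologies],
    ]

    def body_row(token: str, name: str, labels: dict[str, str],
                 codes: list[SemanticCode]) -> list[str]:
        by_term = {sc.terminology: sc.code for sc in codes}
        return [token, name,
                *(labels.get(lang, "") for lang in model.languages),
                *(by_term.get(term, "") for term in terminologies)]

    for group in model.groups:
        rows.append(body_row("itemgroup", group.name, group.labels, group.codes))
        for it in group.items:
            rows.append(body_row(it.datatype, it.name, it.labels, it.codes))
            if it.codelist_oid:
                cl = model.codelist(it.codelist_oid)
                if cl:
                    for cli in cl.items:
                        rows.append(body_row("codelistitem", cli.coded_value,
                                             cli.decodes, cli.codes))
    return CellGrid(rows=rows, origin="memory")


def _normalize_cell(value: object) -> str:
    """Undo spreadsheet numeric coercion: integer-valued floats become '1'."""
    if value is None:
        return ""
    if isinstance(value, bool):
        return "TRUE" if value else "FALSE"
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def load_grid(path: str | Path) -> CellGrid:
    """Read a grid from ``.csv`` (RFC 4180, UTF-8) or ``.xlsx`` (first sheet)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        with open(path, newline="", encoding="utf-8-sig") as fh:
            rows = [list(row) for row in csv.reader(fh)]
        return CellGrid(rows=rows, origin=str(path))
    if suffix == ".xlsx":
        import openpyxl

        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
        ws = wb.worksheets[0]
        rows = [[_normalize_cell(c) for c in row] for row in ws.iter_rows(values_only=True)]
        wb.close()
        return CellGrid(rows=rows, origin=f"{path}!{ws.title}")
    raise OfficeFormatError(f"unsupported extension {suffix!r} (use .csv or .xlsx)")


def save_grid(grid: CellGrid, path: str | Path) -> None:
    """Write a grid as ``.csv`` or ``.xlsx``, chosen by extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            csv.writer(fh).writerows(grid.rows)
        return
    if suffix == ".xlsx":
        import openpyxl

        wb = openpyxl.Workbook()
        ws = wb.active
        for row in grid.rows:
            ws.append(list(row) or [None])
        wb.save(path)
        return
    raise OfficeFormatError(f"unsupported extension {suffix!r} (use .csv or .xlsx)")
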