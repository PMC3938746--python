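"""Structural comparison of two study models.

Verifies that a conversion preserved the form: same item groups, same
items, same datatypes, labels, permissible values and — crucially — the
same semantic annotations at every level.  Matching is by exact (group
name, item name) text; OIDs are assignment artifacts and ignored.  This
is an identity check, not a semantic-similarity score: two forms are
equivalent exactly when nothing differs after canonicalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import CodeList, Item, ItemGroup, StudyModel, canonicalize


@dataclass(frozen=True)
class Change:
    location: str  # item name, "group:<name>" or "<item>[<coded value>]"
    kind: str  # datatype | labels | codes | codelist
    value_a: str
    value_b: str


@dataclass
class DiffReport:
    only_in_a: list[str] = field(default_factory=list)
    only_in_b: list[str] = field(default_factory=list)
    changed: list[Change] = field(default_factory=list)
    group_diffs: list[Change] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    @property
    def equivalent(self) -> bool:
        return not (self.only_in_a or self.only_in_b or self.changed
                    or self.group_diffs or self.errors)

    def describe(self) -> str:
        if self.equivalent:
            return "models are equivalent"
        lines = []
        for name in self.only_in_a:
            lines.append(f"only in A: {name}")
        for name in self.only_in_b:
            lines.append(f"only in B: {name}")
        for ch in self.group_diffs + self.changed:
            lines.append(f"changed {ch.location} [{ch.kind}]: "
                         f"{ch.value_a!r} -> {ch.value_b!r}")
        lines.extend(f"error: {e}" for e in self.errors)
        return "\n".join(lines)


def _codes_repr(codes) -> str:
    return "; ".join(f"{c.terminology}={c.code}" for c in codes)


def _diff_codes(loc: str, a_codes, b_codes, out: list[Change]) -> None:
    sa, sb = set(a_codes), set(b_codes)
    if sa != sb:
        out.append(Change(loc, "codes",
                          _codes_repr(sorted(sa - sb)),
                          _codes_repr(sorted(sb - sa))))


def _diff_labels(loc: str, a_labels: dict, b_labels: dict,
                 out: list[Change]) -> None:
    for lang in sorted(set(a_labels) | set(b_labels)):
        la, lb = a_labels.get(lang, ""), b_labels.get(lang, "")
        if la != lb:
            out.append(Change(f"{loc} ({lang})", "labels", la, lb))


def _diff_codelists(item_name: str, a: CodeList | None, b: CodeList | None,
                    out: list[Change]) -> None:
    a_items = {e.coded_value: e for e in a.items} if a else {}
    b_items = {e.coded_value: e for e in b.items} if b else {}
    if (a is None) != (b is None):
        out.append(Change(item_name, "codelist",
                          "code list present" if a else "no code list",
                          "code list present" if b else "no code list"))
        return
    for coded in sorted(set(a_items) | set(b_items)):
        loc = f"{item_name}[{coded}]"
        ea, eb = a_items.get(coded), b_items.get(coded)
        if ea is None or eb is None:
            out.append(Change(loc, "codelist",
                              "present" if ea else "absent",
                              "present" if eb else "absent"))
            continue
        _diff_labels(loc, ea.decodes, eb.decodes, out)
        _diff_codes(loc, ea.codes, eb.codes, out)


def _by_name(entities, kind: str, errors: list[str]) -> dict[str, object]:
    out: dict[str, object] = {}
    for ent in entities:
        if ent.name in out:
            errors.append(f"duplicate {kind} name {ent.name!r}; matching is by"
                          " name and cannot proceed for this entry")
        out[ent.name] = ent
    return out


def diff_models(a: StudyModel, b: StudyModel) -> DiffReport:
    """Compare two models structurally, after canonicalization.

    Groups are matched by name; items by name within their matched group.
    For matched items the datatype, per-language labels, annotation sets
    and code-list content (coded values, decodes, value-level codes) are
    compared.  Duplicate names break by-name matching and are reported as
    errors rather than guessed around.
    """
    a, b = canonicalize(a), canonicalize(b)
    report = DiffReport()
    groups_a = _by_name(a.groups, "itemgroup", report.errors)
    groups_b = _by_name(b.groups, "itemgroup", report.errors)
    for gname in list(groups_a) + [g for g in groups_b if g not in groups_a]:
        ga: ItemGroup | None = groups_a.get(gname)
        gb: ItemGroup | None = groups_b.get(gname)
        if ga is None or gb is None:
            target = report.only_in_a if gb is None else report.only_in_b
            present = ga or gb
            assert present is not None
            target.append(f"itemgroup {gname}")
            target.extend(f"{gname}/{it.name}" for it in present.items)
            continue
        _diff_labels(f"group:{gname}", ga.labels, gb.labels, report.group_diffs)
        _diff_codes(f"group:{gname}", ga.codes, gb.codes, report.group_diffs)
        items_a = _by_name(ga.items, "item", report.errors)
        items_b = _by_name(gb.items, "item", report.errors)
        for iname in list(items_a) + [i for i in items_b if i not in items_a]:
            ia: Item | None = items_a.get(iname)
            ib: Item | None = items_b.get(iname)
            if ia is None or ib is None:
                target = report.only_in_a if ib is None else report.only_in_b
                target.append(f"{gname}/{iname}")
                continue
            if ia.datatype != ib.datatype:
                report.changed.append(Change(iname, "datatype",
                                             ia.datatype, ib.datatype))
            _diff_labels(iname, ia.labels, ib.labels, report.changed)
            _diff_codes(iname, ia.codes, ib.codes, report.changed)
            cla = a.codelist(ia.codelist_oid) if ia.codelist_oid else None
            clb = b.codelist(ib.codelist_oid) if ib.codelist_oid else None
            _diff_codelists(iname, cla, clb, report.changed)
    return report


def models_equivalent(a: StudyModel, b: StudyModel) -> bool:
    """True iff the two models are structurally identical (OIDs aside)."""
    return diff_models(a, b).equivalent
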