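"""Seeded generation of synthetic study models, plus the worked example.

Real-world annotated CRFs in public model repositories run to tens of
items and a few hundred annotation codes per form; the generator defaults
are calibrated to that scale (roughly 6–33 items across a handful of
groups, up to a few hundred codes).  Pseudo-terminologies use a
``TERM-<k>`` designation and ``T<k>:<n>`` code values so a generated code
can never collide with a real UMLS/SNOMED/LOINC code.  Because the office
template stores at most one code per terminology per row, the generator
draws each entity's annotations from distinct terminologies.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .model import (
    CODED_DATATYPES, CodeList, CodeListItem, Item, ItemGroup, SemanticCode,
    StudyHeader, StudyModel, assign_oids,
)


@dataclass
class SynthSpec:
    """Knobs for the generator; defaults emulate a mid-sized annotated CRF."""

    n_groups: int = 3
    items_per_group: tuple[int, int] = (2, 11)
    datatype_weights: dict[str, float] = field(default_factory=lambda: {
        "string": 3.0, "integer": 3.0, "float": 2.0, "boolean": 1.5,
        "date": 1.0, "time": 0.5})
    codelist_probability: float = 0.4
    codelist_entries: tuple[int, int] = (2, 5)
    codes_per_entity: tuple[int, int] = (2, 8)
    terminologies: tuple[str, ...] = tuple(f"TERM-{k}" for k in range(1, 9))
    languages: tuple[str, ...] = ("en",)
    seed: int = 0

    def check(self) -> None:
        if self.n_groups < 0:
            raise ValueError("n_groups must be >= 0")
        for lo, hi in (self.items_per_group, self.codelist_entries,
                       self.codes_per_entity):
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid count range ({lo}, {hi})")
        if not 0.0 <= self.codelist_probability <= 1.0:
            raise ValueError("codelist_probability must be in [0, 1]")
        if not self.datatype_weights or min(self.datatype_weights.values()) < 0 \
                or max(self.datatype_weights.values()) <= 0:
            raise ValueError("datatype_weights needs at least one positive weight")
        if self.codes_per_entity[1] > len(self.terminologies):
            raise ValueError("codes_per_entity exceeds number of terminologies"
                             " (one code per terminology per entity)")


_WORDS = ("Alpha", "Beta", "Gamma", "Delta", "Epsilon", "Zeta", "Theta",
          "Kappa", "Lambda", "Sigma", "Omega", "Nova", "Orion", "Vega",
          "Lyra", "Atlas")


def generate_model(spec: SynthSpec) -> StudyModel:
    """Generate a deterministic, valid study model from the spec and seed."""
    spec.check()
    rng = random.Random(spec.seed)
    terms = list(spec.terminologies)
    datatypes = list(spec.datatype_weights)
    weights = [spec.datatype_weights[d] for d in datatypes]

    def codes() -> list[SemanticCode]:
        n = rng.randint(*spec.codes_per_entity)
        chosen = rng.sample(terms, n)
        return [SemanticCode(t, f"T{terms.index(t) + 1}:{rng.randint(1, 999999)}")
                for t in chosen]

    def labels(base: str) -> dict[str, str]:
        return {lang: f"{base} ({lang})" for lang in spec.languages}

    header = StudyHeader(
        study_oid=f"S.{rng.randint(0, 9999):04d}",
        sponsor=f"{rng.choice(_WORDS)} Sponsor",
        condition=f"{rng.choice(_WORDS)} Condition",
        study_name=f"{rng.choice(_WORDS)} Study {rng.randint(1, 99)}",
        study_description=f"Synthetic study model, seed {spec.seed}",
        form_name=f"Form-{rng.randint(1, 99)}",
        contact_first_name=rng.choice(_WORDS),
        contact_last_name=f"{rng.choice(_WORDS)}son",
        contact_organization=f"{rng.choice(_WORDS)} Hospital")
    model = StudyModel(header=header, languages=list(spec.languages))
    item_no = 0
    for g in range(1, spec.n_groups + 1):
        gname = f"{rng.choice(_WORDS)}Group{g}"
        group = ItemGroup(oid="", name=gname, labels=labels(gname), codes=codes())
        model.groups.append(group)
        for _ in range(rng.randint(*spec.items_per_group)):
            item_no += 1
            datatype = rng.choices(datatypes, weights)[0]
            name = f"{rng.choice(_WORDS)}{item_no}"
            item = Item(oid="", name=name, datatype=datatype,
                        labels=labels(name), codes=codes())
            group.items.append(item)
            if (datatype in CODED_DATATYPES
                    and rng.random() < spec.codelist_probability):
                cl = CodeList(oid=f"tmp{item_no}", datatype=datatype)
                for v in range(1, rng.randint(*spec.codelist_entries) + 1):
                    coded = str(v) if datatype == "integer" else f"V{v}"
                    cl.items.append(CodeListItem(
                        coded, labels(f"{name} choice {v}"), codes()))
                item.codelist_oid = cl.oid
                model.codelists.append(cl)
    return assign_oids(model)


def fixture_table1() -> StudyModel:
    """The worked-example form: one group, 8 items, 12 semantic codes.

    A small demographics/lab form ("ODM-Test") annotated with UMLS,
    SNOMED CT and LOINC codes — e.g. the Gender item's permissible value
    "male" carries UMLS C0024554 and SNOMED CT 248153007, and the serum
    creatinine item carries LOINC 38483-4.
    """
    umls = "UMLS CUI"
    sct = "SNOMED CT 2010_0731"
    header = StudyHeader(
        study_oid="S.0000", sponsor="Testsponsor", condition="Testcondition",
        study_name="ODM Test Study", study_description="Test of ODM tools",
        form_name="ODM-Test", contact_first_name="Test",
        contact_last_name="Testname", contact_organization="Test organization")
    gender_cl = CodeList(oid="tmp", datatype="integer", items=[
        CodeListItem("1", {"en": "male"},
                     [SemanticCode(umls, "C0024554"), SemanticCode(sct, "248153007")]),
        CodeListItem("2", {"en": "female"},
                     [SemanticCode(umls, "C0015780"), SemanticCode(sct, "248152002")]),
    ])
    info = ItemGroup(
        oid="", name="Info", labels={"en": "General Information"},
        codes=[SemanticCode(umls, "C0332118"), SemanticCode(sct, "106227002")],
        items=[
            Item("", "Willingness", "boolean",
                 {"en": "Willingness to participate in clinical trials"},
                 [SemanticCode(umls, "C1516879")]),
            Item("", "Age", "integer", {"en": "Age"},
                 [SemanticCode(sct, "102518004")]),
            Item("", "DOB", "date", {"en": "Date of Birth"},
                 [SemanticCode(sct, "152322001")]),
            Item("", "Gender", "integer", {"en": "Gender"},
                 [SemanticCode(sct, "139865004")], codelist_oid="tmp"),
            Item("", "DiagnosisTx", "string", {"en": "Diagnosis text"},
                 [SemanticCode(sct, "439401001")]),
            Item("", "DiagnosisCd", "string", {"en": "Diagnosis code"}),
            Item("", "Crea", "float", {"en": "Creatinine"},
                 [SemanticCode("LOINC", "38483-4")]),
            Item("", "labTime", "time", {"en": "Time of lab value"}),
        ])
    model = StudyModel(header=header, groups=[info], codelists=[gender_cl],
                       languages=["en"])
    return assign_oids(model)
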