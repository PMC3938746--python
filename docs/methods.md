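# Methods

## The canonical model and what "lossless" means

All converters share one in-memory structure (`odmconvert.model.StudyModel`):
a study header (OID, sponsor, condition, name, description, form name,
contact), ordered item groups, ordered items (six datatypes: boolean,
integer, date, float, string, time), optional code lists of permissible
values on integer/string items, and semantic annotations — (terminology
designation, code value) pairs — at group, item and permissible-value
level. Terminology designations are opaque text ("SNOMED CT 2010_0731",
"UMLS CUI", "LOINC"); the package never interprets or version-checks them.

Round-trip claims are stated against the *canonical* form of a model.
`canonicalize` trims surrounding whitespace, drops code lists no item
references, sorts each annotation collection by (terminology, code) —
annotation order carries no meaning, so set semantics must hold — and
prunes declared languages that never occur in a label or decode (a
language that annotates nothing is unobservable in the ODM encoding and
would otherwise break the equality). It is idempotent, and every reader
(`read_office`, `read_odm`, `from_stats`) returns a canonical model, so
the contracts are plain dataclass equalities:

```
read_office(write_office(m)) == canonicalize(m)
read_odm(write_odm(m))       == canonicalize(m)
from_stats(to_stats(m))      == canonicalize(m)
```

`assign_oids` gives deterministic identifiers in document order: items
`I.001` … (zero-padded to ≥ 3 digits, widening past 999 items), groups
`IG.1` …, code lists `CL.<owning item OID>`, form `F.1`. OIDs are
assignment artifacts; the form comparison ignores them.

## The three representations

**Office template.** A cell grid: nine header key/value rows (matched by
key label, not row position — investigators reorder rows), a blank row, a
column-header row (`Type`, `Name`, then language columns, then an
open-ended set of terminology columns), then one row per group
(`itemgroup`), item (its datatype token) or permissible value
(`codelistitem`, attached to the most recent item). A language column is
recognized as a 2–3 letter lowercase tag; the first non-tag header starts
the terminology columns. One cell holds at most one code, so an entity
can carry at most one code per terminology — an inherent limit of this
layout, respected by the generator. Cells are text throughout; on XLSX
read, spreadsheet numeric coercion is undone (a numeric cell `1.0`
becomes the coded value `"1"`). CSV is RFC 4180, UTF-8; XLSX uses the
first worksheet only.

**CDISC ODM 1.3.** One `Study`/`MetaDataVersion`/`FormDef` per model
(`FileType="Snapshot"`, `Granularity="Metadata"`, `ODMVersion="1.3.1"`;
the creation timestamp is injectable for reproducible output). Labels
become `Description`/`Question`/`Decode` `TranslatedText` per language;
every annotation becomes exactly one `Alias` and vice versa. Two header
fields have no native ODM 1.3 slot: Sponsor and Condition ride as
reversible `Sponsor: …` / `Condition: …` lines prefixed to
`GlobalVariables/StudyDescription` (stripped on read); the contact goes
to `AdminData/User` (OID `USR.1`). This is a dialect of this tool — other
producers encode these fields differently or not at all. Foreign files
are read leniently: first `FormDef` with a warning if several, unknown
datatypes mapped to the nearest supported one (`datetime`/`text`/partial
dates → string, `double` → float) with a warning, scheduling and
measurement metadata ignored with a warning. An ODM XSD is not bundled
(CDISC distributes it under its own terms); `validate_against_schema`
accepts a locally supplied XSD, and the CLI's `--schema` option wires it
in.

**Labelled dataset.** One column per item, named by item OID, zero rows
for a pure metadata transfer; storage classes boolean→logical,
integer→integer, float→real, date/time/string→text. Variable labels and
value labels carry the chosen display language; the sidecar additionally
records item names, all label languages, value-level codes, group
membership and the original datatype, so the inverse conversion loses
nothing (date/time/string all store as text and would otherwise be
indistinguishable). Coded values stay text even for integer items —
codes are identifiers, not magnitudes. On disk: `<name>.csv` plus
`<name>.meta.json` (shape documented in
`docs/labelled-dataset.meta.schema.json`); the loader enforces the
contract itself. Missing values are empty CSV cells. Subject-level rows
can be appended from an ODM document's `ClinicalData` section
(`attach_clinical_data`): one row per `SubjectData`, values typed per
storage class, unknown item OIDs dropped with a warning, uncoercible
values rejected naming subject and item.

## Form comparison

`diff_models` canonicalizes both models, matches groups by name and items
by name within their group, and compares datatype, per-language labels,
annotation sets and code-list content (coded values, decodes, value-level
codes). The check is identity, not similarity scoring: `equivalent` is
true exactly when nothing differs. Duplicate names within a scope break
by-name matching and are reported as errors, never guessed around. OIDs
are ignored throughout. The diff is symmetric up to swapping sides.

## Synthetic models

`generate_model(SynthSpec)` produces deterministic, valid models from a
seed. Defaults emulate a mid-sized annotated CRF, calibrated to the scale
of real annotated forms in public model repositories (roughly 5–33 items
and tens to a few hundred annotation codes per form): 3 groups of 2–11
items, datatypes weighted toward string/integer, 40 % of eligible items
get a 2–5 value code list, and every entity draws 2–8 codes from distinct
pseudo-terminologies (`TERM-k`, code pattern `Tk:<n>`, chosen so
collisions with real UMLS/SNOMED/LOINC codes are impossible). Across
seeds 1–100 this yields 7–32 items and ~70–390 codes per form.

What the generator does *not* emulate: real terminology codes and their
semantics, multiple codes from the same terminology on one entity (the
office layout cannot carry them), shared code lists across items, items
outside any group, and clinical-data values beyond the small typed
fixtures used for `attach_clinical_data`. Passing round-trip tests
therefore demonstrate structural losslessness of the converters, not the
clinical adequacy of any annotation.

`fixture_table1()` returns the built-in worked example (1 group, 8 items,
12 codes) used throughout the tests and the acceptance script. Its "male"
value carries UMLS C0024554 and SNOMED CT 248153007; creatinine carries
LOINC 38483-4 (the source table typesets this as "38483–4" with an
en-dash; the fixture uses the ASCII hyphen LOINC itself prints).

## Numerical and design choices

* Model equality ignores file bytes; serializers are free in whitespace.
* Header keys in the office template are matched case-sensitively by
  label; `StudyOID` and `Form` are required, the rest default to empty.
* Empty annotation cells mean *no code*; an empty-string code is never
  created.
* The terminology column order on office write is first-occurrence order
  over the document; language order is the model's language order.
* Items belong to exactly one group (a tree, not a DAG) — every
  representation in scope implies this.
* `to_stats` canonicalizes its input first, so the dataset projection is
  stable: `to_stats(from_stats(ds)) == ds`.
* Validation (`validate_model`) reports rather than raises; converters
  that need a usable model raise on `error`-severity findings only.

## Problem sizes

The default test suite drives the worked example plus 100 seeded
synthetic forms (~70–390 codes each) through all three round trips and
runs in a few seconds on one CPU; the acceptance script adds a five-seed
synthetic batch on top of the worked-example chain. These sizes match the
scale of the published multi-form evaluations the generator emulates.

## Known limitations

* Single form per model: no `StudyEventDef` scheduling, multi-form
  studies or versioned model history.
* No MedDRA-style value coding workflows, no regulatory validation, no
  vendor extensions, no digital signatures.
* SPSS/SAS binary exports are out of scope; the CSV + sidecar pair is
  the round-trip carrier.
* A model whose entity carries two codes from the same terminology
  cannot be represented in the office grid (one column per terminology).
* Foreign ODM ingestion keeps what the model covers and warns about the
  rest; it is not a general ODM validator.
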