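# odmconvert

Clinical studies keep three parallel copies of the same data model. The
principal investigator drafts the case report forms (CRFs) in a
spreadsheet; the data manager builds the study database from a CDISC ODM
metadata document; the statistician receives a labelled dataset. Keeping
hundreds of items — and the UMLS / SNOMED CT / LOINC codes that pin down
what each item *means* — synchronized by hand across those three
representations is slow and error-prone.

`odmconvert` converts a study data model losslessly between:

* an **office template** — a plain cell grid (CSV or XLSX) with a
  9-line study header and one line per item group, data item or
  permissible value; one column per language, one column per terminology;
* a **CDISC ODM 1.3** metadata document — `FormDef` / `ItemGroupDef` /
  `ItemDef` / `CodeList`, with every semantic annotation carried as an
  `Alias` element (`Context` = terminology designation, `Name` = code);
* a **labelled statistics dataset** — one column per item named by its
  OID (`I.001` …), variable labels, value labels (e.g. `1 → male`),
  study attributes and all semantic codes, stored as a CSV table plus a
  JSON metadata sidecar.

Semantic annotations are preserved at all three levels (item group, item,
permissible value), and a structural form comparison verifies that any
round trip reproduced identical items and identical annotations.

## Worked example

`examples/table1.csv` is a small demographics/lab form: one item group
("Info"), 8 items (Willingness, Age, DOB, Gender, DiagnosisTx,
DiagnosisCd, Crea, labTime), a Gender code list (1 = male, 2 = female)
and 12 semantic annotations — e.g. SNOMED CT 248153007 on "male" and
LOINC 38483-4 on the creatinine item.

```python
>>> import odmconvert as oc
>>> m = oc.read_office(oc.load_grid("examples/table1.csv"))
>>> sum(len(g.items) for g in m.groups), oc.count_codes(m)
(8, 12)
>>> ds = oc.to_stats(m)
>>> [c.column_id for c in ds.columns]
['I.001', 'I.002', 'I.003', 'I.004', 'I.005', 'I.006', 'I.007', 'I.008']
>>> ds.value_labels["I.004"]
{'1': 'male', '2': 'female'}
>>> back = oc.from_stats(ds)            # statistics -> model
>>> oc.models_equivalent(m, oc.read_odm(oc.write_odm(back)))
True
```

8 items in, 8 `ItemDef`s and 8 OID-named variables out, 12 annotations
everywhere, and the full office → ODM → statistics → ODM chain returns
the identical form.

The same is available from the shell:

```sh
odmconvert office2odm examples/table1.csv form.xml
odmconvert odm2stats form.xml study        # writes study.csv + study.meta.json
odmconvert stats2odm study.csv form2.xml
odmconvert diff form.xml form2.xml         # exit 0: equivalent
odmconvert roundtrip form.xml --via stats  # one-shot round-trip check
odmconvert synth demo.xml --seed 7         # seeded synthetic form
```

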