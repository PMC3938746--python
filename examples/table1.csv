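StudyOID,S.0000
Sponsor,Testsponsor
Condition,Testcondition
StudyName,ODM Test Study
StudyDescription,Test of ODM tools
Form,ODM-Test
FirstName,Test
LastName,Testname
Organization,Test organization

Type,Name,en,UMLS CUI,SNOMED CT 2010_0731,LOINC
itemgroup,Info,General Information,C0332118,106227002,
boolean,Willingness,Willingness to participate in clinical trials,C1516879,,
integer,Age,Age,,102518004,
date,DOB,Date of Birth,,152322001,
integer,Gender,Gender,,139865004,
codelistitem,1,male,C0024554,248153007,
codelistitem,2,female,C0015780,248152002,
string,DiagnosisTx,Diagnosis text,,439401001,
string,DiagnosisCd,Diagnosis code,,,
float,Crea,Creatinine,,,38483-4
time,labTime,Time of lab value,,,
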