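# Default de-identification tag policy: keyword <TAB> action [<TAB> parameter]
# Actions: remove | replace (parameter = new value) | redact (parameter =
# regex whose matches are masked) | keep.  PatientID and PatientName are
# always rewritten to the generated DeID-MRN by the engine itself; dates are
# interval-preservingly shifted by a stored per-patient offset unless listed
# here.  This default is a reasonable baseline and must be reviewed against
# institutional and regulatory requirements before use on real patient data.
PatientBirthDate	remove
PatientBirthTime	remove
PatientAge	remove
PatientAddress	remove
PatientTelephoneNumbers	remove
OtherPatientIDs	remove
OtherPatientNames	remove
PatientMotherBirthName	remove
MilitaryRank	remove
EthnicGroup	remove
Occupation	remove
AdditionalPatientHistory	remove
ReferringPhysicianName	remove
PerformingPhysicianName	remove
PhysiciansOfRecord	remove
OperatorsName	remove
NameOfPhysiciansReadingStudy	remove
RequestingPhysician	remove
InstitutionName	remove
InstitutionAddress	remove
InstitutionalDepartmentName	remove
StationName	remove
DeviceSerialNumber	remove
AccessionNumber	replace
StudyID	replace	DEID
StudyDescription	redact	(?i)mrn\s*\d+
PatientSex	keep
PatientWeight	keep
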