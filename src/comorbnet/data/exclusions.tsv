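# Default code-exclusion list: physical injuries, fever and vomiting.
# The concepts come from the study design; the concrete code sets are an
# editable convention (ICD-10 injury chapters S/T, fever R50, nausea and
# vomiting R11; ICD-9 injury block 800-999, fever 780.6, vomiting 787.0).
# Columns: version <TAB> pattern <TAB> category <TAB> role
ICD9	800.x-999.x	injury	exclusion
ICD9	780.6x	fever	exclusion
ICD9	787.0x	vomiting	exclusion
ICD10	S00.x-S99.x	injury	exclusion
ICD10	T00.x-T98.x	injury	exclusion
ICD10	R50.x	fever	exclusion
ICD10	R11.x	vomiting	exclusion
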