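# Default code-set registry.  Matching is by prefix on normalised codes
# (uppercase, dots removed): a code matches a set iff it starts with an
# include prefix and with no exclude prefix.  Edit or replace this file (and
# point the pipeline config at it) to swap drug or diagnosis lists without
# code changes.

# ICD-10 depressive disorders, three-character blocks F32-F39.
# F35-F38 are unused/reserved blocks in ICD-10; listing them is harmless.
DEPRESSION:
  include: [F32, F33, F34, F35, F36, F37, F38, F39]

# ICD-10 manic episode / bipolar affective disorder.
BIPOLAR_DX:
  include: [F30, F31]

# ATC antidepressants: the whole N06A section except oxitriptan (N06AX01),
# which is not used as an antidepressant marker.
ANTIDEPRESSANT:
  include: [N06A]
  exclude: [N06AX01]

# Specific bipolar-disorder treatments: lithium (N05AN01), valproic acid /
# divalproex (N03AG01) and valpromide (N03AG02).  The WHO ATC index does not
# distinguish divalproex from plain valproic acid, so N03AG01 covers both;
# narrow or widen here if a national drug dictionary separates them.
BIPOLAR_DRUG:
  include: [N05AN01, N03AG01, N03AG02]

# Profiling-only psychotropic classes (cohort characteristics tables).
ANXIOLYTIC:
  include: [N05B]

HYPNOTIC:
  include: [N05C]

# Antipsychotics: N05A minus the lithium subgroup N05AN.
NEUROLEPTIC:
  include: [N05A]
  exclude: [N05AN]
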