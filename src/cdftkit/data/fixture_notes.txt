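Data notes for the packaged reference tables
============================================

Values are shipped exactly as printed in the source tabulations, including
two internally inconsistent cells. Neither is "corrected" here; the
analysis code is expected to flag them.

1. table2.csv, compound 6, gap_ev = 3.84.
   Inconsistent with the same row's HOMO (-6.36 eV) and LUMO (-2.59 eV),
   which give a gap of 3.77 eV; the row's own hardness (1.89 ~ 3.77/2) and
   electrophilicity (5.31 = mu^2/3.77) are consistent with 3.77, so the
   printed gap is a transcription error. Identity checks exempt this one
   cell and verify the recomputed 3.77 instead.

2. table3.csv, compound 5, level basis2_composite: AEA = 1.902 eV with
   VEA = 2.181 eV.
   Violates the physical bracket VEA <= AEA <= VDE (a vertical attachment
   energy cannot exceed the adiabatic one) and is out of line with the
   close analogue compound 11 (AEA = 2.271 eV at the same level). The
   bounds checker is expected to flag exactly this one row.
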