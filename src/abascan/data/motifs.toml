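# Default motif set: candidate ABA-binding site motifs and the secondary
# motifs scanned alongside them.  Syntax: anchors are canonical residue
# letters or bracketed residue classes; `.` is any single residue;
# `.{m,n}` is a flexible gap of m..n residues.
ABA_STRINGENT = "D.{7,8}R.{3,4}D.{5,6}Y.{6,7}H"
ABA_RELAXED = "D.{7,8}R.{8,10}Y.{6,7}H"
AC_TEXT = "[RSK][YFW][DE].{8,12}[RK].{1,3}[DE]"
AC_FIG = "[RSK].[DE].{8,12}[RK].{1,3}[DE]"
SH3 = "[VILAR]P.[VILAR]P"
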