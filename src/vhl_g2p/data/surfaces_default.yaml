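# Default pVHL binding-surface definitions (pVHL30 numbering, 1-213).
#
# The per-surface residue counts (A:35, B:43, C:49, D:59, E:23) match the
# denominators used when normalizing mutated positions per interface.  The
# exact residue memberships are a best-effort reconstruction as contiguous
# ranges consistent with every published residue-to-surface assignment
# (e.g. Arg167 on A, Tyr98 on B, Ala149 on C, Ser33/38/43 on D, Arg200 on E);
# override with your own file for a different partition.
#
# A: alpha-domain face assembling the VCB complex (Elongin-B/C, Cullin-2)
# B: beta-domain face carrying the HIF-1alpha substrate site
# C: beta-domain face toward Cullin-2
# D: pVHL30-specific N-terminal acidic tail
# E: C-terminal tail
surfaces:
  A: "155-189"
  B: "63-105"
  C: "106-154"
  D: "1-59"
  E: "191-213"
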