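# Curated NBS (NB-ARC) domain motif library, in canonical N-to-C order.
#
# Each pattern position is a residue class (a string of allowed amino
# acids); the first residue of each class is the consensus.  min_score is
# the minimum number of matching positions for a hit (defaults to 80% of
# the width when omitted).  Widths stay within the conventional 6-50 aa
# range for NBS motif discovery.
motifs:
  - name: P-loop
    pattern: [G, "MIV", G, G, "LMIV", G, K, T, T]
  - name: RNBS-A
    pattern: [F, "DN", "LIV", "KR", "AT", W, "VI", "CS", "VI", S]
  - name: Kinase-2
    pattern: [K, R, "FY", "LI", "LIV", V, "LF", D, D, "VI", "WD"]
  - name: RNBS-B
    pattern: [G, S, "KR", "IV", "IV", "IVL", T, T, R, "DN"]
  - name: RNBS-C
    pattern: ["YF", E, "VL", "EQ", "PA", L, "SN", "ED", D, "EA", "AS", W]
  - name: GLPL
    pattern: ["CS", G, G, "LV", P, L, A, "LIV", "KI", "TV"]
  - name: RNBS-D
    pattern: [C, F, "LA", Y, C, "AS", "LI", F, P, "EK", "DG", "YH"]
  - name: MHDL
    pattern: [M, H, D, "LV", "LV", R, "DE", "LM", A]
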