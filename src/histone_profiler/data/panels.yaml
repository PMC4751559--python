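# Curated histone-code residue panels, 1-based on the mature human
# reference (initiator Met removed, so H3K4 is literally residue 4).
# Positions are validated against the bundled references at load time.
H3:
  - {name: H3R2,  pos: 2,  residue: R}
  - {name: H3T3,  pos: 3,  residue: T}
  - {name: H3K4,  pos: 4,  residue: K}
  - {name: H3T6,  pos: 6,  residue: T}
  - {name: H3K9,  pos: 9,  residue: K}
  - {name: H3S10, pos: 10, residue: S}
  - {name: H3T11, pos: 11, residue: T}
  - {name: H3K14, pos: 14, residue: K}
  - {name: H3K18, pos: 18, residue: K}
  - {name: H3K23, pos: 23, residue: K}
  - {name: H3K27, pos: 27, residue: K}
  - {name: H3S28, pos: 28, residue: S}
  - {name: H3P30, pos: 30, residue: P}
  - {name: H3K36, pos: 36, residue: K}
  - {name: H3P38, pos: 38, residue: P}
  - {name: H3K56, pos: 56, residue: K}
  - {name: H3K64, pos: 64, residue: K}
  - {name: H3K79, pos: 79, residue: K}
H4:
  - {name: H4S1,  pos: 1,  residue: S}
  - {name: H4R3,  pos: 3,  residue: R}
  - {name: H4K5,  pos: 5,  residue: K}
  - {name: H4K8,  pos: 8,  residue: K}
  - {name: H4K12, pos: 12, residue: K}
  - {name: H4K16, pos: 16, residue: K}
  - {name: H4K20, pos: 20, residue: K}
  - {name: H4K59, pos: 59, residue: K}
  - {name: H4K79, pos: 79, residue: K}
  - {name: H4K91, pos: 91, residue: K}
H2A:
  # N-tail acetyl-lysines of mature human H2A type 1 sit at 5/9/13/15.
  - {name: H2AS1,   pos: 1,   residue: S}
  - {name: H2AK5,   pos: 5,   residue: K}
  - {name: H2AK9,   pos: 9,   residue: K}
  - {name: H2AK13,  pos: 13,  residue: K}
  - {name: H2AK15,  pos: 15,  residue: K}
  - {name: H2AY57,  pos: 57,  residue: Y}
  - {name: H2AK119, pos: 119, residue: K}
  - {name: H2AT120, pos: 120, residue: T}
  - {name: H2AS122, pos: 122, residue: S}
H2B:
  - {name: H2BK5,   pos: 5,   residue: K}
  - {name: H2BK12,  pos: 12,  residue: K}
  - {name: H2BK16,  pos: 16,  residue: K}
  - {name: H2BK20,  pos: 20,  residue: K}
  - {name: H2BK120, pos: 120, residue: K}
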