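# Domain-combination rules for the chromatin-toolkit census.
# Each category names the Pfam-style domains it requires with minimum
# copy numbers; a protein receives every category whose requirements
# its accepted architecture satisfies. Domain names are editable data:
# complexes without a single canonical Pfam accession (CAF-1, HIRA,
# Spt16, Dot1, PRMT5, Rpb1) ship with documented default choices.
remodeler-core: {SWI2_N: 1, Helicase_C: 1}
CHD-type:       {Chromo: 1, SWI2_N: 1, Helicase_C: 1}
ISWI-type:      {SLIDE: 1, SWI2_N: 1, Helicase_C: 1}
INO80-type:     {DBINO: 1, SWI2_N: 1, Helicase_C: 1}
SWIB:           {SWIB: 1}
SWIRM:          {SWIRM: 1}
GNAT:           {Acetyltransf_1: 1}
KAT11:          {KAT11: 1}
MOZ_SAS:        {MOZ_SAS: 1}
NuA4:           {NuA4: 1}
HDAC:           {Hist_deacetyl: 1}
SIR2:           {SIR2: 1}
SET:            {SET: 1}
Dot1:           {DOT1: 1}
PRMT5:          {PRMT5: 1}
JmjC:           {JmjC: 1}
Bromo-reader:   {Bromodomain: 1}
Chromo-reader:  {Chromo: 1}
PHD-reader:     {PHD: 1}
Tudor-reader:   {Tudor: 1}
PWWP-reader:    {PWWP: 1}
WD40:           {WD40: 1}
HP1:            {Chromo: 2, Chromo_shadow: 1}
Spt16:          {SPT16: 1}
SSRP1:          {SSrecog: 1}
NAP1:           {NAP: 1}
CAF-1:          {CAF1C_H4-bd: 1}
HIRA:           {HIRA_B: 1}
ASF1:           {ASF1_hist_chap: 1}
Rpb1:           {RNA_pol_Rpb1_5: 1}
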