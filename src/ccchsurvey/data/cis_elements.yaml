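# Editable cis-element lexicon: name -> IUPAC pattern + source note.
# These are the widely used PLACE-style cores for the two classic
# abiotic-stress elements; databases print slightly different variants, so
# edit or extend this file to match your reference of choice.
ABRE:
  pattern: ACGTG
  note: >-
    ABA-responsive element core (ACGT-containing G-box half-site), as in
    PLACE ABRELATERD1/ABRE-like entries.
DRE:
  pattern: RCCGAC
  note: >-
    Dehydration-responsive element / C-repeat (DRE/CRT) core, R = A/G, as in
    PLACE DRECRTCOREAT.
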