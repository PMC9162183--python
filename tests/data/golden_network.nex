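#NEXUS

BEGIN TAXA;
  DIMENSIONS NTAX=3;
  TAXLABELS
    trad
    modern
    'wild sp'
  ;
END;

BEGIN DISTANCES;
  DIMENSIONS NTAX=3;
  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;
  MATRIX
    trad 0 0.25 0.5
    modern 0.25 0 0.125
    'wild sp' 0.5 0.125 0
  ;
END;
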