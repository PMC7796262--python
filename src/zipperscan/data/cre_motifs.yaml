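# Default cis-regulatory element table for promoter scanning.
#
# The A-box, C-box, and G-box sequences are the canonical ACGT-core boxes
# of plant bZIP binding sites. Every other pattern is this package's
# transcription of the public PlantCARE consensus for the named element;
# edit freely -- the scanner treats this file as configuration, not ground
# truth. Patterns are IUPAC nucleotide strings; categories follow the
# conventional development / hormone / stress / core grouping.
motifs:
  - {name: A-box,        pattern: TACGTA,    category: core}
  - {name: C-box,        pattern: GACGTC,    category: core}
  - {name: G-box,        pattern: CACGTG,    category: core}
  - {name: CAAT-box,     pattern: CCAAT,     category: core}
  - {name: CAT-box,      pattern: GCCACT,    category: development}
  - {name: HD-Zip1,      pattern: CAATWATTG, category: development}
  - {name: AE-box,       pattern: AGAAACAA,  category: development}
  - {name: Box4,         pattern: ATTAAT,    category: development}
  - {name: ABRE,         pattern: ACGTG,     category: hormone}
  - {name: TGA-element,  pattern: AACGAC,    category: hormone}
  - {name: CGTCA-motif,  pattern: CGTCA,     category: hormone}
  - {name: GARE-motif,   pattern: TCTGTTG,   category: hormone}
  - {name: AuxRR-core,   pattern: GGTCCAT,   category: hormone}
  - {name: ARE,          pattern: AAACCA,    category: stress}
  - {name: LTR,          pattern: CCGAAA,    category: stress}
  - {name: MBS,          pattern: CAACTG,    category: stress}
  - {name: TC-rich,     pattern: ATTCTCTAAC, category: stress}
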