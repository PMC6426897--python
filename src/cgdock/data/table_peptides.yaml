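# Registry of the ten designed/template peptides.
# sequence: 1-letter codes, '*' marks the two hydrocarbon-staple positions
#   (i and i+7); 'X' padding of the published table is stripped.
# template: which helix-2 template the row derives from, with the operations
#   (staple position, mutations as pos: "orig>new") that reconstruct it.
# All peptides are N-acetylated (ACE) and C-amidated (NHE).
peptides:
  - name: "wt_ASC_PYD"
    sequence: "TAEELKKFKLKLLSV"
    template: "ASC_helix2"
    staple: null
    mutations: {}
  - name: "wts_ASC_PYD#1"
    sequence: "TAEE*KKFKLK*LSV"
    template: "ASC_helix2"
    staple: 5
    mutations: {}
  - name: "ms_ASC_PYD#2"
    sequence: "TARE*KKAKFK*ESV"
    template: "ASC_helix2"
    staple: 5
    mutations: {3: "E>R", 8: "F>A", 10: "L>F", 13: "L>E"}
  - name: "ms_ASC_PYD#3"
    sequence: "TARV*KKAKFK*ESV"
    template: "ASC_helix2"
    staple: 5
    mutations: {3: "E>R", 4: "E>V", 8: "F>A", 10: "L>F", 13: "L>E"}
  - name: "ms_ASC_PYD#4"
    sequence: "TARA*KVAKFK*ESV"
    template: "ASC_helix2"
    staple: 5
    mutations: {3: "E>R", 4: "E>A", 7: "K>V", 8: "F>A", 10: "L>F", 13: "L>E"}
  - name: "ms_ASC_PYD#5"
    sequence: "TARA*KLAKIK*ESV"
    template: "ASC_helix2"
    staple: 5
    mutations: {3: "E>R", 4: "E>A", 7: "K>L", 8: "F>A", 10: "L>I", 13: "L>E"}
  - name: "ms_ASC_PYD#6"
    sequence: "RA*KKAKIK*ESV"
    template: "ASC_helix2_short"
    staple: 3
    mutations: {1: "E>R", 2: "E>A", 6: "F>A", 8: "L>I", 11: "L>E"}
  - name: "wt_NLRP3_PYD"
    sequence: "VDLKKFKMHLEDY"
    template: "NLRP3_helix2"
    staple: null
    mutations: {}
  - name: "m_NLRP3_PYD"
    sequence: "VDLKKAKFHLEDY"
    template: "NLRP3_helix2"
    staple: null
    mutations: {6: "F>A", 8: "M>F"}
  - name: "ms_NLRP3_PYD"
    sequence: "VD*KKAKFH*EDY"
    template: "NLRP3_helix2"
    staple: 3
    mutations: {6: "F>A", 8: "M>F"}
templates:
  ASC_helix2: "TAEELKKFKLKLLSV"    # pyrin-domain helix 2, residues 16-30
  ASC_helix2_short: "EELKKFKLKLLSV"  # residues 18-30 (two fewer N-terminal residues)
  NLRP3_helix2: "VDLKKFKMHLEDY"    # NLRP3 pyrin-domain helix 2, residues 20-32
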