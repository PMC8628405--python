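# Small example simulation: two clades of three references plus one query
# each, a two-leaf outgroup, and a planted counterion-style contrast at
# site 30 (E in cladeA, F in cladeB).
newick: "((OUT1:0.1,OUT2:0.1):0.3,((A1:0.1,A2:0.1,A3:0.1,QA:0.1):0.3,(B1:0.1,B2:0.1,B3:0.1,QB:0.1):0.3):0.3);"
root_seq_length: 120
clades:
  cladeA: [A1, A2, A3, QA]
  cladeB: [B1, B2, B3, QB]
outgroup: [OUT1, OUT2]
constrained_sites:
  30:
    cladeA: E
    cladeB: F
seed: 20211129
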