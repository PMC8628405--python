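# Opsin functional-site scheme in bovine rhodopsin numbering.
# Reference: Bos taurus rhodopsin, 348 aa (UniProt P02699); positions are
# 1-based indices into this sequence, matching the literature numbering.
scheme_id = bovine_rhodopsin
reference = MNGTEGPNFYVPFSNKTGVVRSPFEAPQYYLAEPWQFSMLAAYMFLLIMLGFPINFLTLYVTVQHKKLRTPLNYILLNLAVADLFMVFGGFTTTLYTSLHGYFVFGPTGCNLEGFFATLGGEIALWSLVVLAIERYVVVCKPMSNFRFGENHAIMGVAFTWVMALACAAPPLVGWSRYIPEGMQCSCGIDYYTPHEETNNESFVIYMFVVHFIIPLIVIFFCYGQLVFTVKEAAAQQQESATTQKAEKEVTRMVIIMVIAFLICWLPYAGVAFYIFTHQGSDFGPIFMTIPAFFAKTSAVYNPVIYIMMNKQFRNCMVTTLCCGKNPLGDDEASTTVSKTETSQVAPA

# Schiff-base counterion of monostable visual pigments.
site = E113=113:E:counterion

# Residue pairs stabilizing the active state / coupling to the G protein,
# plus the anchored residues of the NPXXY motif (302-306).
site = D83=83:D:gprotein
site = N302=302:N:gprotein
site = R135=135:R:gprotein
site = Y223=223:Y:gprotein
site = K231=231:K:gprotein
site = E247=247:E:gprotein
site = Y306=306:Y:gprotein
site = F313=313:F:gprotein
site = P303=303:P:gprotein

pair = D83/N302=D83,N302
pair = R135/Y223=R135,Y223
pair = K231/E247=K231,E247
pair = Y306/F313=Y306,F313

motif = NPXXY=302:N,303:P,306:Y
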