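# RLBP1 (CRALBP) retinoid-binding scheme in human RLBP1 numbering.
#
# SYNTHETIC REFERENCE BACKBONE.  The backbone below is not the human RLBP1
# protein (UniProt P12271); it is a fixed pseudo-random 317-residue stand-in
# that carries the ten retinoid-binding-critical residues (W166, Y180, F198,
# C199, M209, Q211, M223, V224, M226, W245) at their literature positions,
# so that site mapping and the 10-site conservation score behave exactly as
# they would against the real sequence.  To score published orthologs
# against the genuine human protein, supply a user scheme config whose
# reference line is the P12271 sequence (positions below are unchanged).
scheme_id = human_RLBP1
reference = LNEDDVMFNLEGSSCFKLSWQRKSVMERNACARFTYCEQGQEDMHGWREWENYIWCTFRAQGDSHQLAPRTHRSDSQHKYKGYDPAFIEMNLLNRVNGKELICWYGNDEVPLTRWIWKGEGFDAGKTHVAAMPAPNFMDASHFINFCLWFSNVPTHLDFNEYYFKWRCICGRGPHGTREYWRWCRIWTLYSIAKIIFFCEMDRRWVPCMPQCWIWITRGQEHMVNMNDQIMPGYQDFDHAKKSLWNWSWQMFLSETIQLDRRVEWELEWSFFLHFTESLDRLLSWSWGFRWPQMIHWISCKVGFPYKYKPLLLRRST

# The ten residues critical for retinoid binding (site-directed mutagenesis).
site = W166=166:W:rlbp1_critical
site = Y180=180:Y:rlbp1_critical
site = F198=198:F:rlbp1_critical
site = C199=199:C:rlbp1_critical
site = M209=209:M:rlbp1_critical
site = Q211=211:Q:rlbp1_critical
site = M223=223:M:rlbp1_critical
site = V224=224:V:rlbp1_critical
site = M226=226:M:rlbp1_critical
site = W245=245:W:rlbp1_critical
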