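# PPR recognition-code table: nucleotide preference of a PPR motif from
# the identities of its 5th and 35th residues.  Entries follow the
# combinatorial code established for plant PPR proteins (T/S/N/G at the
# 5th position combined with N/D/S at the 35th).  The wildcard "." in a
# column matches any residue; lookups try the exact pair first, then
# (aa5, .), then (., aa35), then (., .), and finally fall back to N
# (any nucleotide).  Override with --code-table to supply your own.
#
# aa5	aa35	nucleotides
T	N	A
S	N	A
T	D	G
S	D	G
N	D	T
G	D	T
N	S	C
N	N	CT
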