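"""Published oligonucleotide sequences for the SCRCA platform.

These are the printed primer, split-oligo and tag sequences from the
platform's wet-lab protocol.  They serve as reference fixtures: designed
oligos are checked against the shapes and homologies these exhibit (e.g.
the 15-nt junction homology between the two block-gene primer sets).
"""

#: Split DNA templating ligation of the two-unit (RLP+ELP) large ring.
RE_SPLIT_OLIGO = "ACCAGGAACACCATCACCACGACC"

#: Inverse-PCR primers that linearize the expression vector while adding
#: the MK N-terminal and WPTHHHHHH C-terminal tags.
VECTOR_C_TERM_PRIMER = "TGGCCGACTCATCATCACCACCACCAC"
VECTOR_N_TERM_PRIMER = "TTCATATGTATATCTCCTTCTTAAAGTTAAAC"

#: Primer pair producing RLP-block genes for simultaneous two-fragment
#: cloning.  The reverse primer's 5' extension encodes the junction that
#: recognizes the 5' end of the ELP-block genes.
RLP_BLOCK_FWD_PRIMER = "GATATACATATGAAAGGGCGCGGTGACTCTCC"
RLP_BLOCK_REV_PRIMER = "GACACCTACTGAGTAAGGTGAATCACCACGACC"

#: Primer pair producing ELP-block genes for the same reaction.
ELP_BLOCK_FWD_PRIMER = "TACTCAGTAGGTGTCCCAGGTGTCGG"
ELP_BLOCK_REV_PRIMER = "ATGATGAGTCGGCCAACCAGGAACACCAACACCAGGTAC"

#: Colony-PCR / Sanger sequencing primers flanking the insert.
T7_PROMOTER_PRIMER = "TAATACGACTCACTATAGG"
T7_TERMINATOR_PRIMER = "GCTAGTTATTGCTCAGCGG"

#: Amplicon-library primers with sequencing linkers at their 5' ends.
NGS_FWD_PRIMER = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAGTGTAGGTGTCCCAGGTGTCGG"
NGS_REV_PRIMER = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAGACCAGGAACACCAACACCAGGTAC"

#: Expression-tag peptides added around the repeat tract.
N_TERM_TAG = "MK"
C_TERM_TAG = "WPTHHHHHH"
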