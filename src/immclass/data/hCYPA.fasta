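>hCYPA human cyclophilin A (accession P62937)
MVNPTVFFDIAVDGEPLGRVSFELFADKVPKTAENFRALSTGEKGFGYKGSCFHRIIPGF
MCQGGDFTRHNGTGGKSIYGEKFEDENFILKHTGPGILSMANAGPNTNGSQFFICTAKTE
WLDGKHVVFGKVKEGMNIVEAMERFGSRNGKTSKKITIADCGQLE
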