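# Curated methylation-sensitive type II restriction enzymes.
# recognition is IUPAC; cut offsets are nt from the 5' end of the
# recognition site on the top/bottom strand; sensitivity means the enzyme
# is blocked by CpG methylation within its site. User-extensible; entries
# are validated on load (type II cutting strictly inside the site, exactly
# one CpG dinucleotide when methylation-sensitive).
name	recognition	cut_top	cut_bottom	methylation_sensitive
HhaI	GCGC	3	1	true
HpaII	CCGG	1	3	true
AciI	CCGC	1	3	true
HpyCH4IV	ACGT	1	3	true
ClaI	ATCGAT	2	4	true
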