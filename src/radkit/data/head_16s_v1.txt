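# SSU head residue set, E. coli 16S rRNA numbering, version 1.
# The head is the 3' major domain of the 16S rRNA; residues are listed as
# inclusive ranges "start end", one per line.  Everything matched to the 16S
# outside these ranges belongs to the body.
# This is an operational, versioned definition of the head/body partition;
# downstream results are reproducible against this exact list.
921 1396
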