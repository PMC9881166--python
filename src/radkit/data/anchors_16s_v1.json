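{
  "version": 1,
  "comment": "Zero-tilt-direction anchor residue sets in E. coli 16S numbering. h44: helix 44 (the penultimate stem; its turn is 1450-1453) anchors the body psi=0 direction. a_site/e_site: decoding-site and E-site codon-region proxy residues anchoring the head psi=0 direction (E-site -> A-site vector, roughly the mRNA binding track).",
  "h44": {"ranges": [[1404, 1499]]},
  "h44_turn": {"residues": [1450, 1451, 1452, 1453]},
  "a_site": {"residues": [530, 1408, 1492, 1493]},
  "e_site": {"residues": [693, 795]}
}
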