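# Epitope definitions for `ampedit consequence --epitopes`.
# Each entry is a 1-based inclusive residue interval on the full
# wildtype protein. Y188 is the C-terminal APP antibody recognizing the
# last 20 residues of the 695-residue isoform; its loss in a predicted
# product reports a successful C-terminal truncation.
- name: Y188
  start: 676
  end: 695
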