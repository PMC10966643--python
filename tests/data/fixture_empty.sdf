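empty-ligand
  degenerate

  0  0  0  0  0  0  0  0  0  0999 V2000
M  END
$$$$
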