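fixture-ligand
  hand-built 3D

  4  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.4000    0.2000    0.1000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8000    1.1000   -0.5000 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.3000   -1.3000    0.7000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
$$$$
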