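C-x(2)-C-x(4)-[LIVMF]-x(2)-[ST]-x(3)-C
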