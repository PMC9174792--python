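(((iso_1:0.1,iso_2:0.1):0.5,iso_3:0.6):0.4,((iso_4:0.2,iso_5:0.2):0.3,iso_6:0.5):0.5);
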