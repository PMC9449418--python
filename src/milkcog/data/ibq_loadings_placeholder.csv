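subscale,sur,neg,reg
ibq_01,1,0,0
ibq_02,1,0,0
ibq_03,1,0,0
ibq_04,1,0,0
ibq_05,1,0,0
ibq_06,1,0,0
ibq_07,0,1,0
ibq_08,0,1,0
ibq_09,0,1,0
ibq_10,0,1,0
ibq_11,0,0,1
ibq_12,0,0,1
ibq_13,0,0,1
ibq_14,0,0,1
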