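{
 "table1.csv": "e26bba7d3cc461d4c66debdb20184d9e566ab250eb3510083f777b727c8a6ee4",
 "table2.csv": "b1c3b5dd12299a97ff2f2e63579c1191a427903fdfe7cd5e9533a05e527375dd",
 "worked_example.json": "35c3b07802934a276c5c49788a66f091a7a0340aea141864eda7bb21ca0276c6"
}
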