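6. cluster$ adj2 randomi$.tw.
7. ((communit$ adj2 intervention$) OR (communit$ adj2 randomi$)).tw.
8. group$ randomi$.tw.
9. 6 OR 7 OR 8
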