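10. intervention?.tw.
11. cluster analysis/
12. health promotion/
13. program evaluation/
14. health education/
15. 10 OR 11 OR 12 OR 13 OR 14
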