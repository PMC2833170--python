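1. randomized controlled trial.pt.
2. animals/
3. humans/
4. 2 NOT (2 AND 3)
5. 1 NOT 4
6. cluster$ adj2 randomi$.tw.
7. ((communit$ adj2 intervention$) OR (communit$ adj2 randomi$)).tw.
8. group$ randomi$.tw.
9. 6 OR 7 OR 8
10. intervention?.tw.
11. cluster analysis/
12. health promotion/
13. program evaluation/
14. health education/
15. 10 OR 11 OR 12 OR 13 OR 14
16. 9 OR 15
18. 16 AND 5
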