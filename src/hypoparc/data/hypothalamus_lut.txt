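# id name R G B A region partner
1 L-Ant-Hypothalamus 255 170 0 0 hypothalamic-anterior 2
2 R-Ant-Hypothalamus 255 200 60 0 hypothalamic-anterior 1
3 L-Med-Hypothalamus 0 120 255 0 hypothalamic-middle 4
4 R-Med-Hypothalamus 80 170 255 0 hypothalamic-middle 3
5 L-Lat-Hypothalamus 0 180 90 0 hypothalamic-middle 6
6 R-Lat-Hypothalamus 90 220 140 0 hypothalamic-middle 5
7 Tuberal-region 170 0 255 0 hypothalamic-middle 0
8 L-Post-Hypothalamus 255 0 90 0 hypothalamic-posterior 9
9 R-Post-Hypothalamus 255 90 150 0 hypothalamic-posterior 8
10 L-C-Mammilare 140 90 40 0 hypothalamic-posterior 11
11 R-C-Mammilare 190 140 80 0 hypothalamic-posterior 10
12 3rd-Ventricle 60 60 60 0 others 0
13 L-Fornix 220 220 0 0 others 14
14 R-Fornix 250 250 90 0 others 13
15 Epiphysis 0 200 200 0 others 0
16 Hypophysis 200 0 200 0 others 0
17 Infundibulum 120 120 255 0 others 0
18 Ant-Commisure 255 120 120 0 others 0
19 L-N-Opticus 0 90 0 0 optic 20
20 R-N-Opticus 60 150 60 0 optic 19
21 L-Chiasma-Opticus 90 0 90 0 optic 22
22 R-Chiasma-Opticus 150 60 150 0 optic 21
23 L-Optic-tract 0 0 140 0 optic 24
24 R-Optic-tract 70 70 200 0 optic 23
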