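# id name R G B A region partner
1 Ventricle 60 60 60 0 others 0
2 L-Nucleus 255 170 0 0 hypothalamic-middle 3
3 R-Nucleus 255 220 90 0 hypothalamic-middle 2
4 L-Optic-tube 0 120 255 0 optic 5
5 R-Optic-tube 90 180 255 0 optic 4
6 Commissure 200 0 200 0 others 0
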