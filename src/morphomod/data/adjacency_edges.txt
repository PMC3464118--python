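# Default anatomical adjacency for the 16-landmark hemimandible outline:
# consecutive landmarks around the outline, closed into a cycle.
1 2
2 3
3 4
4 5
5 6
6 7
7 8
8 9
9 10
10 11
11 12
12 13
13 14
14 15
15 16
16 1
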