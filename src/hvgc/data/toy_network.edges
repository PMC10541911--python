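# 10-node toy network: a 4-node leaf cluster bridged by node 3 to a dense core.
3	1
3	2
3	4
3	5
5	6
5	7
5	8
6	7
7	8
7	9
8	9
9	10
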