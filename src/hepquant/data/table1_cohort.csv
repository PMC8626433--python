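lesion_id,grade,pct_positive,intensity,reduction_rate,growth_pattern,volume_cm3,ishak
1,G1,0.90,+++,0.67,conventional,196.1,1
2,G1,0.95,+++,0.59,conventional,837.4,0
3,G1,0.30,+++,0.49,conventional,114.6,6
4,G1,0.30,+++,0.57,conventional,118.6,6
5,G1,0.15,++,0.31,conventional,530.1,2
6,G2,0.20,++,0.24,conventional,282.9,6
7,G1,0.20,++,0.47,conventional,184.3,4
8,G2,0.50,++,0.37,conventional,135.3,0
9,G1,0.40,++,0.53,conventional,168.9,5
10,G1,0.05,+++,0.40,conventional,9.1,3
11,G2,0.03,+++,0.32,conventional,66.8,6
12,G1,0.03,++,0.17,conventional,11.4,6
13,G2,0.02,++,0.29,conventional,6.1,2
14,G2,0.01,++,0.12,conventional,285.8,6
15,G2,0.05,+,0.22,conventional,47.1,6
16,G1,0.05,+,0.30,conventional,0.2,0
17,G1,0.03,+,0.29,conventional,442.9,0
18,G3,0.00,0,0.32,macrotrabecular,20.7,4
19,G2,0.00,0,0.19,conventional,55.1,4
20,G3,0.00,0,0.23,conventional,682.3,2
21,G2,0.00,0,0.36,scirrhous,24.3,1
22,G1,0.00,0,0.21,steatohepatitic,24.1,6
23,G1,0.00,0,0.36,steatohepatitic,4.9,6
24,G1,0.00,0,0.31,conventional,560.8,1
25,G3,0.00,0,0.31,conventional,10.3,3
26,G2,0.00,0,0.31,conventional,71.5,6
27,G2,0.00,0,0.15,macrotrabecular,127.1,6
28,G2,0.00,0,0.23,conventional,17.1,0
29,G3,0.00,0,0.15,conventional,274.9,6
30,G3,0.00,0,0.23,conventional,108.8,5
31,G2,0.00,0,0.29,conventional,25.9,1
32,G2,0.00,0,0.22,conventional,40.4,1
33,G2,0.00,0,0.26,conventional,155.4,1
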