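spiked_mg_per_L,day,measured_mg_per_L
0.44,0,0.46
0.44,7,0.46
0.44,14,0.46
0.44,21,0.43
0.44,28,0.43
0.44,42,0.45
0.44,56,0.45
0.44,70,0.40
0.44,84,0.43
0.44,112,0.42
0.44,140,0.42
0.44,168,0.39
0.44,196,0.35
0.44,224,0.37
0.44,252,0.36
0.44,280,0.32
0.44,308,0.30
0.44,336,0.32
0.44,364,0.32
4.38,0,4.37
4.38,7,4.47
4.38,14,4.44
4.38,21,4.18
4.38,28,4.15
4.38,42,4.26
4.38,56,4.21
4.38,70,4.02
4.38,84,4.10
4.38,112,3.97
4.38,140,3.77
4.38,168,3.74
4.38,196,3.46
4.38,224,3.55
4.38,252,3.38
4.38,280,2.90
4.38,308,2.61
4.38,336,2.86
4.38,364,2.77
17.5,0,16.4
17.5,7,17.8
17.5,14,17.0
17.5,21,15.3
17.5,28,15.5
17.5,42,16.3
17.5,56,16.0
17.5,70,14.6
17.5,84,15.0
17.5,112,14.5
17.5,140,13.8
17.5,168,12.6
17.5,196,11.6
17.5,224,12.4
17.5,252,11.4
17.5,280,10.2
17.5,308,8.8
17.5,336,10.1
17.5,364,9.4
35.1,0,33.2
35.1,7,34.5
35.1,14,33.5
35.1,21,30.2
35.1,28,29.9
35.1,42,31.8
35.1,56,31.1
35.1,70,28.5
35.1,84,29.3
35.1,112,27.9
35.1,140,26.4
35.1,168,24.5
35.1,196,21.8
35.1,224,23.0
35.1,252,20.7
35.1,280,18.9
35.1,308,16.2
35.1,336,18.3
35.1,364,16.9
52.6,0,50.3
52.6,7,52.1
52.6,14,50.6
52.6,21,46.2
52.6,28,43.5
52.6,42,47.5
52.6,56,46.1
52.6,70,41.2
52.6,84,41.9
52.6,112,42.1
52.6,140,38.1
52.6,168,35.5
52.6,196,31.0
52.6,224,32.9
52.6,252,30.4
52.6,280,26.2
52.6,308,22.4
52.6,336,26.7
52.6,364,24.2
70.1,0,67.5
70.1,7,68.7
70.1,14,67.2
70.1,21,61.2
70.1,28,59.3
70.1,42,62.8
70.1,56,62.2
70.1,70,58.5
70.1,84,58.8
70.1,112,55.8
70.1,140,50.7
70.1,168,48.6
70.1,196,43.4
70.1,224,45.8
70.1,252,41.1
70.1,280,37.1
70.1,308,31.8
70.1,336,37.2
70.1,364,32.7
87.6,0,83.3
87.6,7,86.9
87.6,14,84.2
87.6,21,75.8
87.6,28,73.7
87.6,42,79.0
87.6,56,79.0
87.6,70,72.6
87.6,84,70.2
87.6,112,69.1
87.6,140,65.5
87.6,168,61.7
87.6,196,54.7
87.6,224,57.7
87.6,252,51.3
87.6,280,47.1
87.6,308,37.5
87.6,336,45.1
87.6,364,40.6
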