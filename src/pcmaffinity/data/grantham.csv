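,A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V
A,0,111.411,110.564,125.914,195.261,90.881,106.853,60.074,85.606,93.786,96.314,105.710,84.551,112.730,26.910,99.263,58.100,147.921,111.735,64.515
R,111.411,0,85.226,95.940,179.772,42.870,54.090,125.294,28.857,97.715,102.015,26.038,91.759,97.161,102.850,109.357,71.065,101.424,77.209,95.923
N,110.564,85.226,0,23.036,138.949,45.813,40.913,79.450,68.445,149.110,152.532,94.006,141.339,158.321,90.276,46.301,64.860,174.011,142.417,133.053
D,125.914,95.940,23.036,0,153.777,61.365,44.663,93.891,81.345,168.303,171.984,101.591,160.238,176.759,108.052,65.557,85.188,190.804,160.148,152.214
C,195.261,179.772,138.949,153.777,0,154.434,169.661,158.440,174.072,197.510,197.689,201.845,195.812,204.658,168.813,111.820,149.126,214.645,193.980,191.485
Q,90.881,42.870,45.813,61.365,154.434,0,29.312,87.281,24.116,108.709,112.590,53.299,101.032,115.739,75.235,68.288,41.159,130.376,98.914,96.453
E,106.853,54.090,40.913,44.663,169.661,29.312,0,97.981,40.848,134.339,138.525,56.943,126.251,140.397,93.854,79.893,65.588,152.460,122.939,121.488
G,60.074,125.294,79.450,93.891,158.440,87.281,97.981,0,97.662,135.597,137.873,126.625,127.112,153.327,41.684,55.340,59.234,184.033,147.120,108.931
H,85.606,28.857,68.445,81.345,174.072,24.116,40.848,97.662,0,94.462,98.823,32.446,86.458,100.127,76.378,89.053,46.815,114.712,83.438,84.004
I,93.786,97.715,149.110,168.303,197.510,108.709,134.339,135.597,94.462,0,4.862,101.746,10.134,21.305,95.502,141.985,89.401,60.608,33.091,29.648
L,96.314,102.015,152.532,171.984,197.689,112.590,138.525,137.873,98.823,4.862,0,106.476,14.322,21.853,97.905,144.269,92.476,61.061,35.724,31.827
K,105.710,26.038,94.006,101.591,201.845,53.299,56.943,126.625,32.446,101.746,106.476,0,94.615,102.276,102.849,120.692,77.844,109.579,84.898,97.125
M,84.551,91.759,141.339,160.238,195.812,101.032,126.251,127.112,86.458,10.134,14.322,94.615,0,28.565,86.709,135.042,81.147,66.725,35.269,21.550
F,112.730,97.161,158.321,176.759,204.658,115.739,140.397,153.327,100.127,21.305,21.853,102.276,28.565,0,113.877,155.012,102.994,39.707,21.638,50.001
P,26.910,102.850,90.276,108.052,168.813,75.235,93.854,41.684,76.378,95.502,97.905,102.849,86.709,113.877,0,73.449,37.613,146.814,109.760,67.876
S,99.263,109.357,46.301,65.557,111.820,68.288,79.893,55.340,89.053,141.985,144.269,120.692,135.042,155.012,73.449,0,57.825,176.810,143.296,123.196
T,58.100,71.065,64.860,85.188,149.126,41.159,65.588,59.234,46.815,89.401,92.476,77.844,81.147,102.994,37.613,57.825,0,128.485,92.369,69.588
W,147.921,101.424,174.011,190.804,214.645,130.376,152.460,184.033,114.712,60.608,61.061,109.579,66.725,39.707,146.814,176.810,128.485,0,37.163,88.080
Y,111.735,77.209,142.417,160.148,193.980,98.914,122.939,147.120,83.438,33.091,35.724,84.898,35.269,21.638,109.760,143.296,92.369,37.163,0,54.735
V,64.515,95.923,133.053,152.214,191.485,96.453,121.488,108.931,84.004,29.648,31.827,97.125,21.550,50.001,67.876,123.196,69.588,88.080,54.735,0
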