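Index,Q_Points,R_Peaks,S_Points,T_Points,P_Points
0,316,330,358,429,248
1,791,805,833,904,724
2,1273,1287,1315,1386,1207
3,1712,1726,1754,1794,1645
4,2107,2121,2149,2220,2040
5,2582,2596,2624,2695,2515
6,3064,3078,3106,3177,2997
7,3503,3517,3545,3584,3436
8,3898,3912,3940,4011,3831
9,4373,4387,4415,4486,4306
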