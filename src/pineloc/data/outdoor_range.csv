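row,laser_mm,depth_mm,difference_mm,error_rate_pct
1,196,199,3,1.53
2,287,291,4,1.39
3,307,306,-1,0.33
4,311,311,0,0.00
5,315,316,1,0.32
6,391,385,-6,1.53
7,466,467,1,0.21
8,554,558,4,0.72
9,684,689,5,0.73
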