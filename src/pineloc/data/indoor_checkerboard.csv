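row,ruler_mm,laser_mm,depth_mm,x1,y1,xb,yb,dx_mm,dx_error_pct,dy_mm,dy_error_pct,dz_diff_mm,dz_error_pct,corrected_diff_mm,corrected_error_pct
1,250,244,255,960,540,1298,201,56.10,2.71,-59.85,1.23,11,4.51,5,2.05
2,300,295,302,951,543,661,259,-57.00,1.99,-59.38,1.20,7,2.37,1,0.34
3,350,344,352,985,548,1238,704,57.96,1.43,38.02,1.13,8,2.33,2,0.58
4,400,396,405,956,551,730,343,-59.58,0.85,-58.32,1.15,9,2.27,3,0.76
5,450,445,456,981,545,790,680,-56.69,1.38,42.62,0.14,11,2.27,5,1.12
6,500,493,504,958,553,1124,374,54.46,1.70,-62.46,0.11,11,2.23,5,1.01
7,550,545,552,947,554,793,666,-55.33,1.39,42.80,0.15,7,1.28,1,0.18
8,600,593,605,960,548,1106,642,57.49,0.91,39.37,0.43,12,2.02,6,1.01
9,650,646,650,939,555,800,427,-58.81,0.65,-57.60,0.83,4,0.62,-2,0.31
10,700,693,699,961,555,833,436,-58.24,0.68,-57.59,0.77,6,0.87,0,0.00
11,750,742,750,953,556,1072,628,58.09,0.65,37.39,0.62,8,1.08,2,0.27
12,800,791,795,949,520,1061,625,57.95,0.63,57.79,0.65,4,0.51,-2,0.25
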