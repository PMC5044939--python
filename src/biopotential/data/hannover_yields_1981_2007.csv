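# Observed regional harvest statistics and crop-model predictions, region of
# Hannover, 1981-2007.  Units: silage maize in dt fresh mass/ha, winter wheat
# in dt grain/ha.  Columns *_printed carry the error and adjusted columns as
# printed in the source report (one decimal; a few adjusted wheat values are
# internally inconsistent with factor x prediction and are kept verbatim).
year,maize_obs,maize_pred,maize_e_pct_printed,maize_adjust_printed,maize_ae_pct_printed,wheat_obs,wheat_pred,wheat_e_pct_printed,wheat_adjust_printed,wheat_ae_pct_printed
1981,482.9,753.1,55.9,542.2,12.3,55.1,90.7,64.7,72.6,31.7
1982,491.6,650.7,32.4,468.5,-4.7,64.5,78.7,22.0,62.9,-2.4
1983,400.4,533.2,33.2,383.9,-4.1,61.3,85.8,39.9,68.6,11.9
1984,413.2,642.9,55.6,462.9,12.0,63.3,96.5,52.5,77.2,22.0
1985,468.3,794.2,69.6,571.8,22.1,61.8,87.5,41.5,70.0,13.2
1986,460.5,715.7,55.4,515.3,11.9,78.3,82.0,4.7,65.6,-16.3
1987,427.6,703.0,64.4,506.2,18.4,75.4,83.5,10.8,66.8,-11.3
1988,458.4,528.8,15.4,380.8,-16.9,71.5,73.8,3.2,59.0,-17.4
1989,414.2,418.0,0.9,301.0,-27.3,54.0,79.7,47.7,63.8,18.1
1990,379.8,516.2,35.9,371.6,-2.2,71.9,79.0,9.9,63.2,-12.1
1991,399.0,492.9,23.5,354.9,-11.1,81.3,93.8,15.4,75.0,-7.7
1992,367.8,382.0,3.9,275.1,-25.2,75.3,78.0,3.6,62.4,-17.1
1993,461.0,704.5,52.8,507.2,10.0,82.9,97.5,17.6,78.0,-5.9
1994,429.1,638.6,48.8,459.8,7.2,81.5,96.1,17.9,76.9,-5.6
1995,398.3,569.9,43.1,410.3,3.0,84.2,102.56,21.8,82.1,-2.6
1996,424.7,639.3,50.5,460.3,8.4,82.4,83.4,1.3,66.7,-19.0
1997,460.9,695.1,50.8,500.4,8.6,88.5,111.25,25.7,89.0,0.6
1998,454.5,655.9,44.3,472.3,3.9,82.0,102.68,25.3,82.2,0.2
1999,432.6,632.0,46.1,455.0,5.2,93.5,102.42,9.5,81.9,-12.4
2000,496.3,582.3,17.3,419.3,-15.5,87.7,98.5,12.2,84.8,-3.4
2001,489.7,619.3,26.5,445.9,-8.9,95.4,107.67,12.8,91.8,-3.8
2002,470.7,650.1,38.1,468.1,-0.6,76.4,117.61,54.0,99.3,30.0
2003,375.2,441.1,17.6,317.6,-15.3,78.8,88.2,11.9,73.44,-6.8
2004,480.6,722.4,50.3,520.2,8.2,89.9,125.68,39.7,103.8,15.4
2005,482.2,711.5,47.6,512.3,6.2,84.8,121.74,43.6,99.5,17.3
2006,421.5,581.0,37.9,418.3,-0.7,84.3,102.66,21.8,93.0,-1.6
2007,537.7,771.4,43.5,555.4,3.3,77.5,107.48,38.7,86.0,10.9
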