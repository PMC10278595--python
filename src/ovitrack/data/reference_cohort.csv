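band,female_id,year,winter_ha,summer_ha,overlap_ha,overlap_pct,distance_km,delta_elev_m,n_returns,strategy_printed
1,42696,2019,273.4,2887.8,0.0,0,47.4,-44.0,0,LDM
2,42703,2019,610.8,1810.2,0.0,0,41.0,-31.6,0,LDM
3,42704,2019,650.8,2476.3,0.0,0,31.3,-257.1,0,LDM
3,42701,2019,1195.1,2525.4,0.0,0,30.2,-7.7,0,LDM
4,42698,2019,2308.0,10196.2,0.0,0,26.5,-110.2,0,LDM
4,41320,2019,1750.1,2732.5,516.3,29.5,,-121.7,0,ABR
4,42702,2019,392.6,2453.7,181.0,46.1,,-45.1,0,ABR
5,41324,2019,277.9,4925.8,0.0,0,17.3,-6.8,0,LDM
6,41318,2019,598.5,2459.2,15.0,2.5,15.2,-43.4,0,LDM
6,42699,2019,732.5,3598.0,9.5,1.3,14.0,21.4,0,LDM
7,41321,2018,1852.9,6324.1,163.1,8.8,11.4,62.9,3,V-SDM
7,41323,2018,1738.8,3191.5,0.0,0,10.7,-44.3,3,V-SDM
8,42697,2019,234.5,2770.2,19.9,8.5,7.9,4.9,0,SDM
8,42695,2019,233.6,2325.6,22.7,9.7,7.6,6.6,0,SDM
9,41322,2019,1559.5,3237.7,506.8,32.5,,7.5,0,ABR
9,42700,2019,1521.7,1765.5,1113.9,73.2,,-22.3,0,ABR
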