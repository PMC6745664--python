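period,climate,vegetation,qlow_days,qlow_events,qdiffall_days,qdiffdry_days,q_mm_year
reference,historical,i,187,11,74,33,346
near,rcp45,i,758,31,63,25,272
near,rcp85,i,722,24,49,22,238
near,rcp45,ii,853,32,52,20,240
near,rcp85,ii,802,23,46,17,208
near,rcp45,iii,760,33,61,25,270
near,rcp85,iii,721,24,50,20,236
near,rcp45,iv,1527,58,49,17,196
near,rcp85,iv,1376,39,40,15,166
far,rcp45,i,854,31,54,26,238
far,rcp85,i,1369,62,45,18,165
far,rcp45,ii,936,32,48,22,208
far,rcp85,ii,1533,63,36,15,143
far,rcp45,iii,852,30,54,26,235
far,rcp85,iii,1369,62,43,17,164
far,rcp45,iv,1393,48,46,27,166
far,rcp85,iv,2152,68,34,14,114
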