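test_id,threshold,tp,fp,fn,tn,n_missing_case,n_missing_ctrl,n_inconclusive_case,n_inconclusive_ctrl,n_with_result,sens,sens_lo,sens_hi,spec,spec_lo,spec_hi,ppv,ppv_lo,ppv_hi,npv,npv_lo,npv_hi
rmi1,200,23,29,24,596,2,125,0,0,672,48.9,34.1,63.9,95.4,93.4,96.9,44.2,30.5,58.7,96.1,94.3,97.5
rmi1,250,20,22,27,603,2,125,0,0,672,42.6,28.3,57.8,96.5,94.7,97.8,47.6,32.0,63.6,95.7,93.8,97.2
roma,7.4,43,372,5,330,1,48,0,0,750,89.6,77.3,96.5,47.0,43.3,50.8,10.4,7.6,13.7,98.5,96.6,99.5
roma,11.4,38,189,10,513,1,48,0,0,750,79.2,65.0,89.5,73.1,69.6,76.3,16.7,12.1,22.2,98.1,96.5,99.1
roma,12.5,37,164,11,358,1,48,0,0,750,77.1,62.7,88.0,68.6,64.4,72.5,18.4,13.3,24.5,97.0,94.7,98.5
roma,13.1,36,149,12,553,1,48,0,0,750,75.0,60.4,86.4,78.8,75.6,81.7,19.5,14.0,25.9,97.9,96.3,98.9
adnex,3,43,311,3,260,3,179,0,0,617,93.5,82.1,98.6,45.5,41.4,49.7,12.1,8.9,16.0,98.9,96.7,99.8
adnex,10,41,142,5,429,3,179,0,0,617,89.1,76.4,96.4,75.1,71.4,78.6,22.4,16.6,29.1,98.8,97.3,99.6
srrisk,3,41,231,6,390,2,129,0,0,668,87.2,74.3,95.2,62.8,58.9,66.6,15.1,11.0,19.9,98.5,96.7,99.4
srrisk,10,39,149,8,472,2,129,0,0,668,83.0,69.2,92.4,76.0,72.4,79.3,20.7,15.2,27.2,98.3,96.7,99.3
simple_rules,,24,25,8,496,2,124,15,105,553,75.0,56.6,88.5,95.2,93.0,96.9,49.0,34.4,63.7,98.4,96.9,99.3
ca125,87,27,82,22,664,0,4,0,0,795,55.1,40.2,69.3,89.0,86.5,91.2,24.8,17.0,34.0,96.8,95.2,98.0
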