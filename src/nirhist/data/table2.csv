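matrix_kind,sample_index,nir,hplc,printed_abs_error
raw,1,<LOQ,<LOQ,
raw,2,<LOQ,<LOQ,
raw,3,1694,1279,415
raw,4,18,<LOQ,17.7
raw,5,15.7,<LOQ,15.7
raw,6,34.7,16.4,18.4
raw,7,<LOQ,<LOQ,
raw,8,23,<LOQ,23.2
raw,9,25,<LOQ,24.8
raw,10,12,<LOQ,12.1
raw,11,17,<LOQ,17.4
raw,12,17,<LOQ,16.6
raw,13,32.1,10.9,21.2
raw,14,46.4,18.4,27.9
raw,15,62.5,<LOQ,62.5
raw,16,36,<LOQ,35.7
raw,17,30.9,<LOQ,30.9
raw,18,28,20.8,7.0
raw,19,<LOQ,<LOQ,
raw,20,<LOD,<LOQ,
raw,21,61.9,31.5,30.3
raw,22,33.3,<LOQ,33.3
raw,23,<LOQ,<LOQ,
raw,24,<LOQ,<LOQ,
raw,25,30.18,16.4,13.8
raw,26,25,11.4,13.9
raw,27,<LOQ,<LOQ,
raw,28,<LOD,<LOQ,
raw,29,13.1,<LOQ,13.1
raw,30,<LOD,<LOQ,
raw,31,31.89,18.5,13.4
raw,32,<LOQ,<LOQ,
raw,33,<LOQ,<LOQ,
raw,34,<LOD,<LOQ,
raw,35,<LOQ,<LOQ,
raw,36,<LOQ,<LOQ,
raw,37,60.6,30.8,29.9
raw,38,61.2,27.1,34.1
raw,39,14,<LOQ,14.0
raw,40,<LOQ,<LOQ,
processed,1,75.67,60.1,15.6
processed,2,102.4,94.3,8.1
processed,3,36.2,15.6,20.6
processed,4,32,14.3,17.4
processed,5,15,<LOQ,15.4
processed,6,10,<LOQ,10.0
processed,7,22.1,<LOQ,22.1
processed,8,26.1,<LOQ,26.1
processed,9,52.5,37.2,15.3
processed,10,21.8,<LOQ,21.8
processed,11,83.3,72.4,10.9
processed,12,32.2,15.6,16.7
processed,13,24.7,<LOQ,24.74
processed,14,41.5,25.7,15.8
processed,15,41,24.3,16.6
processed,16,17.6,<LOQ,17.6
processed,17,65.0,40.3,24.7
processed,18,<LOD,<LOQ,
processed,19,<LOD,0.86,
processed,20,<LOQ,<LOQ,8.2
processed,21,<LOD,<LOQ,
processed,22,30.4,15.7,14.8
processed,23,54,40.3,14.1
processed,24,50,22.4,27.8
processed,25,46.1,21.0,25.0
processed,26,<LOD,<LOQ,
processed,27,<LOQ,<LOQ,
processed,28,12,<LOQ,12.2
processed,29,<LOQ,<LOQ,
processed,30,49.9,30.3,19.6
processed,31,56.6,40.9,15.7
processed,32,60.5,30.5,30.1
processed,33,45.8,25.4,20.4
processed,34,46.8,20.7,26.1
processed,35,30.6,15.7,14.9
processed,36,37.2,16.3,20.9
processed,37,29.4,<LOQ,29.4
processed,38,21.5,<LOQ,24.5
processed,39,11.7,<LOQ,11.7
processed,40,<LOQ,<LOQ,
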