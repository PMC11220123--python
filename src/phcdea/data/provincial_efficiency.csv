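province,region,stage1_te,stage1_pte,stage1_se,stage1_rts,stage1_rank,stage3_te,stage3_pte,stage3_se,stage3_rts,stage3_rank,compare
Beijing,east,1,1,1,-,1,0.644,0.889,0.724,irs,20,up
Tianjin,east,0.887,1,0.887,irs,13,0.731,1,0.731,irs,18,up
Hebei,east,0.848,0.853,0.995,drs,16,0.833,0.846,0.985,irs,15,up
Shanxi,central,0.451,0.462,0.975,irs,30,0.437,0.509,0.859,irs,30,up
Inner Mongolia,west,0.51,0.536,0.951,irs,27,0.477,0.596,0.801,irs,27,up
Liaoning,east,0.595,0.603,0.985,irs,25,0.618,0.694,0.89,irs,21,down
Jilin,central,0.488,0.523,0.933,irs,29,0.471,0.598,0.789,irs,28,up
Heilongjiang,central,0.506,0.542,0.933,irs,28,0.544,0.687,0.792,irs,24,down
Shanghai,east,1,1,1,-,2,0.806,1,0.806,irs,16,up
Jiangsu,east,0.887,1,0.887,drs,14,0.911,0.924,0.986,irs,11,down
Zhejiang,east,1,1,1,-,3,1,1,1,-,1,same
Anhui,central,0.927,1,0.927,drs,11,1,1,1,-,1,down
Fujian,east,0.873,0.875,0.999,irs,15,0.804,0.847,0.949,irs,17,up
Jiangxi,central,0.956,0.98,0.976,drs,10,0.987,0.995,0.993,drs,8,down
Shandong,east,0.82,1,0.82,drs,19,0.87,1,0.87,drs,12,down
Henan,central,0.835,0.947,0.882,drs,17,0.839,0.939,0.893,drs,14,down
Hubei,central,0.917,0.991,0.925,drs,12,0.941,0.98,0.96,drs,9,down
Hunan,central,0.826,0.882,0.936,drs,18,0.858,0.892,0.963,drs,13,down
Guangdong,east,1,1,1,-,4,1,1,1,-,1,same
Guangxi,west,0.981,1,0.981,drs,9,1,1,1,-,1,down
Hainan,east,0.694,0.864,0.804,irs,23,0.54,0.987,0.547,irs,25,up
Chongqing,west,1,1,1,-,5,1,1,1,-,1,same
Sichuan,west,0.992,1,0.992,drs,8,1,1,1,-,1,down
Guizhou,west,1,1,1,-,6,1,1,1,-,1,same
Yunnan,west,1,1,1,-,7,0.927,0.992,0.935,irs,10,up
Tibet,west,0.373,1,0.373,irs,31,0.102,0.507,0.201,irs,31,up
Shaanxi,west,0.595,0.614,0.969,irs,26,0.563,0.624,0.902,irs,23,up
Gansu,west,0.761,0.767,0.993,irs,21,0.691,0.789,0.875,irs,19,up
Qinghai,west,0.707,1,0.707,irs,22,0.523,1,0.523,irs,26,up
Ningxia,west,0.776,1,0.776,irs,20,0.464,1,0.464,irs,29,up
Xinjiang,west,0.648,0.714,0.908,irs,24,0.58,0.703,0.826,irs,22,up
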