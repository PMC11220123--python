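year_pair,effch,techch,pech,sech,tfpch
2012-2013,1,1.031,0.992,1.007,1.031
2013-2014,1.017,0.974,0.994,1.023,0.991
2014-2015,0.971,0.953,0.992,0.978,0.926
2015-2016,0.996,1.007,1.017,0.979,1.003
2016-2017,1.027,1,0.996,1.032,1.027
2017-2018,0.96,0.965,0.989,0.97,0.926
2018-2019,0.947,1.015,0.975,0.971,0.961
2019-2020,0.954,0.837,0.999,0.955,0.798
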