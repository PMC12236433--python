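ercc_id	molecules_per_sample
ERCC-00001	10
ERCC-00002	11.64
ERCC-00003	13.55
ERCC-00004	15.77
ERCC-00005	18.35
ERCC-00006	21.36
ERCC-00007	24.87
ERCC-00008	28.94
ERCC-00009	33.69
ERCC-00010	39.21
ERCC-00011	45.64
ERCC-00012	53.12
ERCC-00013	61.83
ERCC-00014	71.97
ERCC-00015	83.77
ERCC-00016	97.5
ERCC-00017	113.5
ERCC-00018	132.1
ERCC-00019	153.7
ERCC-00020	179
ERCC-00021	208.3
ERCC-00022	242.4
ERCC-00023	282.2
ERCC-00024	328.5
ERCC-00025	382.3
ERCC-00026	445
ERCC-00027	517.9
ERCC-00028	602.9
ERCC-00029	701.7
ERCC-00030	816.7
ERCC-00031	950.7
ERCC-00032	1107
ERCC-00033	1288
ERCC-00034	1499
ERCC-00035	1745
ERCC-00036	2031
ERCC-00037	2364
ERCC-00038	2751
ERCC-00039	3203
ERCC-00040	3728
ERCC-00041	4339
ERCC-00042	5050
ERCC-00043	5878
ERCC-00044	6842
ERCC-00045	7963
ERCC-00046	9269
ERCC-00047	10790
ERCC-00048	12560
ERCC-00049	14620
ERCC-00050	17010
ERCC-00051	19800
ERCC-00052	23050
ERCC-00053	26830
ERCC-00054	31230
ERCC-00055	36340
ERCC-00056	42300
ERCC-00057	49240
ERCC-00058	57310
ERCC-00059	66710
ERCC-00060	77640
ERCC-00061	90370
ERCC-00062	105200
ERCC-00063	122400
ERCC-00064	142500
ERCC-00065	165900
ERCC-00066	193100
ERCC-00067	224700
ERCC-00068	261600
ERCC-00069	304500
ERCC-00070	354400
ERCC-00071	412500
ERCC-00072	480100
ERCC-00073	558800
ERCC-00074	650400
ERCC-00075	757000
ERCC-00076	881200
ERCC-00077	1.026e+06
ERCC-00078	1.194e+06
ERCC-00079	1.389e+06
ERCC-00080	1.617e+06
ERCC-00081	1.882e+06
ERCC-00082	2.191e+06
ERCC-00083	2.55e+06
ERCC-00084	2.968e+06
ERCC-00085	3.455e+06
ERCC-00086	4.022e+06
ERCC-00087	4.681e+06
ERCC-00088	5.448e+06
ERCC-00089	6.342e+06
ERCC-00090	7.381e+06
ERCC-00091	8.591e+06
ERCC-00092	1e+07
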