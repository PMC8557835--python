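{
 "selected": [
  "deg_per2",
  "vmax_bmal1",
  "vmax_per2",
  "vmax_ror"
 ],
 "p": 24,
 "parameters": [
  "vmax_bmal1",
  "deg_bmal1",
  "vmax_per2",
  "deg_per2",
  "vmax_cry1",
  "deg_cry1",
  "vmax_reverb",
  "deg_reverb",
  "vmax_ror",
  "deg_ror",
  "vmax_clock",
  "deg_clock",
  "p_clock_c",
  "deg_clock_c",
  "p_bmal_c",
  "deg_bmal_c",
  "k_assoc",
  "deg_cb_n",
  "p_per",
  "deg_per_c",
  "p_cry",
  "deg_cry_c",
  "k_complex",
  "deg_pc_c",
  "k_pc_import",
  "deg_pc_n",
  "p_rev",
  "deg_rev",
  "p_ror",
  "deg_ror_p"
 ],
 "n_samples": 256,
 "seed": 12345,
 "outputs": [
  "rev_erb:mean",
  "rev_erb:amplitude",
  "rev_erb:phase",
  "ror_p:mean",
  "ror_p:amplitude",
  "ror_p:phase",
  "clock_bmal_n:mean",
  "clock_bmal_n:amplitude",
  "clock_bmal_n:phase",
  "per_cry_n:mean",
  "per_cry_n:amplitude",
  "per_cry_n:phase"
 ],
 "indices": [
  [
   0.02583,
   0.01567,
   0.07597,
   0.00992,
   0.00868,
   0.04964,
   0.01768,
   0.00518,
   0.01963,
   0.08184,
   0.0188,
   -0.05976
  ],
  [
   -0.00131,
   0.00436,
   -0.00019,
   0.00933,
   0.00705,
   0.04629,
   0.04731,
   -0.00203,
   0.02693,
   0.02578,
   0.00675,
   0.05236
  ],
  [
   0.03616,
   0.04348,
   -0.09076,
   0.03295,
   0.03783,
   0.27325,
   0.00489,
   0.01263,
   -0.03577,
   0.13147,
   0.04066,
   0.01183
  ],
  [
   0.01412,
   0.00761,
   0.0921,
   0.06032,
   0.05527,
   0.02024,
   0.00264,
   -0.00444,
   -0.04234,
   0.07085,
   0.00432,
   0.08697
  ],
  [
   0.02231,
   0.02512,
   -0.19233,
   -0.0353,
   0.10871,
   -0.10063,
   -0.00753,
   0.00974,
   -0.02874,
   0.24707,
   0.05314,
   -0.12111
  ],
  [
   -0.02684,
   0.01408,
   -0.14516,
   -0.02498,
   -0.0161,
   -0.01877,
   0.00473,
   -0.01803,
   0.01343,
   0.19359,
   0.00685,
   -0.01296
  ],
  [
   0.12919,
   0.03771,
   0.01971,
   0.00908,
   -0.00278,
   -0.01577,
   0.02826,
   -0.00326,
   0.03279,
   0.06554,
   0.06945,
   0.12758
  ],
  [
   0.29984,
   0.12264,
   0.00814,
   0.00879,
   0.05489,
   -0.08261,
   0.00839,
   0.01244,
   0.10026,
   0.11146,
   0.09686,
   -0.03216
  ],
  [
   0.01387,
   0.02094,
   0.09965,
   0.22139,
   0.00365,
   0.11374,
   0.06978,
   0.07635,
   0.0406,
   0.06668,
   0.0187,
   0.02473
  ],
  [
   0.02842,
   0.00234,
   0.01948,
   0.10582,
   0.03053,
   -0.07131,
   0.03033,
   0.01388,
   -0.0003,
   0.0858,
   0.00379,
   0.03294
  ],
  [
   0.0031,
   -0.00239,
   -0.03822,
   0.01432,
   -0.00325,
   0.1109,
   0.07757,
   0.01323,
   -0.10316,
   0.11477,
   -0.00189,
   -0.00839
  ],
  [
   0.00931,
   0.01469,
   0.01499,
   0.0319,
   0.00093,
   0.01682,
   0.10211,
   -0.01047,
   0.01891,
   0.0061,
   -0.00163,
   -0.04139
  ],
  [
   0.00749,
   0.00016,
   0.10477,
   -0.00379,
   0.01195,
   0.04925,
   0.0249,
   0.01834,
   0.03817,
   0.00902,
   -0.00314,
   -0.0053
  ],
  [
   -0.00393,
   -0.02009,
   0.01235,
   0.00559,
   -0.01961,
   -0.00678,
   0.04979,
   -0.01907,
   0.0128,
   0.03166,
   -0.0133,
   -0.02698
  ],
  [
   -0.00229,
   -0.01795,
   0.01681,
   -0.01712,
   -0.0115,
   0.01984,
   -0.01101,
   -0.02189,
   0.05921,
   -0.03953,
   -0.0181,
   0.0622
  ],
  [
   -0.00333,
   0.018,
   -0.0041,
   0.00833,
   0.01654,
   -0.00198,
   0.04111,
   0.04438,
   0.09365,
   0.04627,
   0.01427,
   -0.04733
  ],
  [
   -0.00104,
   0.01475,
   0.0205,
   0.00971,
   0.00943,
   -0.04207,
   0.03971,
   0.00651,
   -0.08201,
   -0.01666,
   0.01282,
   -0.07607
  ],
  [
   0.0249,
   -0.00355,
   0.05459,
   0.00746,
   0.00992,
   -0.04976,
   0.03907,
   -0.00297,
   0.01888,
   0.01356,
   0.00348,
   -0.05856
  ],
  [
   0.13395,
   0.0485,
   0.06298,
   0.02604,
   0.05432,
   0.03364,
   -0.00397,
   -0.02946,
   -0.00807,
   0.07272,
   0.04559,
   -0.15673
  ],
  [
   0.02645,
   0.03824,
   -0.10225,
   0.00258,
   0.00542,
   -0.03014,
   -0.00593,
   0.00903,
   -0.04652,
   0.01994,
   0.04759,
   0.09827
  ],
  [
   -0.01556,
   0.08881,
   0.05632,
   -0.01004,
   0.0207,
   -0.10403,
   -0.00143,
   0.08023,
   -0.1533,
   0.2797,
   0.09649,
   -0.02346
  ],
  [
   0.00424,
   0.03815,
   0.01832,
   -0.01544,
   0.00784,
   -0.1302,
   -0.00317,
   0.00254,
   -0.28845,
   0.03075,
   0.03282,
   0.02218
  ],
  [
   0.00016,
   0.10201,
   -0.12888,
   -0.00354,
   0.07386,
   -0.19577,
   0.00081,
   0.04627,
   -0.05108,
   0.05162,
   0.10796,
   -0.08294
  ],
  [
   0.00352,
   0.00342,
   0.0787,
   0.00017,
   -0.00925,
   0.15884,
   -0.00099,
   -0.0045,
   -0.19589,
   0.00382,
   -0.00047,
   0.15534
  ],
  [
   0.04962,
   0.05072,
   -0.27947,
   -0.00063,
   0.00126,
   -0.01162,
   6e-05,
   -0.05489,
   -0.20574,
   0.10148,
   0.08345,
   -0.06634
  ],
  [
   0.11526,
   0.08694,
   -0.20189,
   0.00823,
   0.20661,
   0.23297,
   0.00517,
   0.02536,
   -0.08169,
   0.11506,
   0.02918,
   0.14591
  ],
  [
   0.04561,
   0.10013,
   0.10588,
   -0.00159,
   0.08211,
   0.04741,
   0.03089,
   0.04274,
   -0.12248,
   0.20188,
   0.13107,
   -0.07617
  ],
  [
   0.07245,
   0.15449,
   0.12907,
   0.00326,
   0.03703,
   0.06319,
   0.03933,
   -0.07521,
   -0.00311,
   0.17771,
   0.07296,
   0.03661
  ],
  [
   0.0027,
   0.00199,
   -0.00169,
   0.23172,
   -0.0023,
   -0.04128,
   0.04713,
   0.05199,
   -0.07906,
   -0.01616,
   0.0059,
   -0.03207
  ],
  [
   -0.00014,
   -0.00466,
   0.04049,
   0.15299,
   0.15108,
   -0.00865,
   0.05134,
   0.00968,
   0.00327,
   0.0461,
   0.0012,
   0.04868
  ]
 ]
}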