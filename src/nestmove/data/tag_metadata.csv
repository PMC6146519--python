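animal,n_argos_raw,n_dives_raw,start,end
131111,173,375,2016-03-23T01:01,2016-03-27T16:25
131115,179,850,2016-02-26T13:20,2016-03-01T13:54
131116,457,1475,2016-02-26T21:28,2016-03-06T14:18
131127,2495,6780,2016-04-26T14:05,2016-07-13T14:01
131128,52,60,2016-04-26T13:25,2016-04-27T06:36
131130,151,1014,2016-04-25T17:53,2016-04-29T17:30
131132,589,1703,2016-04-25T20:23,2016-05-10T14:11
131133,2077,6419,2016-04-26T13:24,2016-07-05T16:04
131134,653,1445,2016-04-26T00:08,2016-05-12T11:31
131136,1970,4874,2016-04-26T13:25,2016-06-29T18:11
154187,486,1380,2016-03-21T20:05,2016-04-02T16:10
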