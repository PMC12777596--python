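case_id,filter,rater,score
1,gaussian,1,4
1,gaussian,2,4
1,nlm,1,5
1,nlm,2,5
2,gaussian,1,4
2,gaussian,2,4
2,nlm,1,5
2,nlm,2,5
3,gaussian,1,4
3,gaussian,2,4
3,nlm,1,5
3,nlm,2,5
4,gaussian,1,5
4,gaussian,2,5
4,nlm,1,5
4,nlm,2,5
5,gaussian,1,4
5,gaussian,2,4
5,nlm,1,5
5,nlm,2,5
6,gaussian,1,4
6,gaussian,2,4
6,nlm,1,5
6,nlm,2,5
7,gaussian,1,4
7,gaussian,2,4
7,nlm,1,5
7,nlm,2,5
8,gaussian,1,3
8,gaussian,2,3
8,nlm,1,4
8,nlm,2,4
9,gaussian,1,5
9,gaussian,2,5
9,nlm,1,5
9,nlm,2,5
10,gaussian,1,4
10,gaussian,2,4
10,nlm,1,5
10,nlm,2,5
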