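band,age_lo,age_hi,weight
0-4,0,4,69135
5-9,5,9,72533
10-14,10,14,73032
15-19,15,19,72169
20-24,20,24,66478
25-29,25,29,64529
30-34,30,34,71044
35-39,35,39,80762
40-44,40,44,81851
45-49,45,49,72118
50-54,50,54,62716
55-59,55,59,48454
60-64,60,64,38793
65-69,65,69,34264
70-74,70,74,31773
75-79,75,79,26999
80-84,80,84,17842
85+,85,120,15508
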