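LM=21
1.25 0
1.180817 -0.32805600000000001
0.99349399999999999 -0.60685900000000004
0.72764099999999998 -0.81309299999999995
0.41680299999999998 -0.94275600000000004
0.084367999999999999 -0.99770599999999998
-0.25211 -0.979437
-0.57618800000000003 -0.88741400000000004
-0.86801899999999999 -0.71955800000000003
-1.0994820000000001 -0.47571400000000003
-1.232318 -0.16758000000000001
-1.232318 0.16758000000000001
-1.0994820000000001 0.47571400000000003
-0.86801899999999999 0.71955800000000003
-0.57618800000000003 0.88741400000000004
-0.25211 0.979437
0.084367999999999999 0.99770599999999998
0.41680299999999998 0.94275600000000004
0.72764099999999998 0.81309299999999995
0.99349399999999999 0.60685900000000004
1.180817 0.32805600000000001
ID=rounded
LM=21
0.68000000000000005 0
0.69678099999999998 -0.27882400000000002
0.70261700000000005 -0.55717700000000003
0.50725500000000001 -0.73203499999999999
0.229106 -0.74720500000000001
-0.048180000000000001 -0.71362899999999996
-0.32121699999999997 -0.65441800000000006
-0.58877400000000002 -0.57398899999999997
-0.84801400000000005 -0.46995999999999999
-1.0908089999999999 -0.33231899999999998
-1.2837799999999999 -0.133434
-1.2837799999999999 0.133434
-1.0908089999999999 0.33231899999999998
-0.84801400000000005 0.46995999999999999
-0.58877400000000002 0.57398899999999997
-0.32121699999999997 0.65441800000000006
-0.048180000000000001 0.71362899999999996
0.229106 0.74720500000000001
0.50725500000000001 0.73203499999999999
0.70261700000000005 0.55717700000000003
0.69678099999999998 0.27882400000000002
ID=reniform
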