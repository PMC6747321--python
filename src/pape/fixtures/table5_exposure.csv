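Start,End,Latitude,Longitude,PM2.5,Environment,Activity,VE,Exposure
2017-03-24 00:00,2017-03-24 11:55,40.461,-3.709,5354.15601,Outdoor,Rest,0.00893,47.81261
2017-03-24 11:55,2017-03-24 11:59,40.459,-3.711,13.9543,Outdoor,Walk,0.01326,0.18503
2017-03-24 11:59,2017-03-24 12:04,40.457,-3.712,20.08333,Outdoor,Rest,0.00893,0.17934
2017-03-24 12:04,2017-03-24 12:23,40.449,-3.701,111.43482,Outdoor,Transport,0.00893,0.99511
2017-03-24 13:16,2017-03-24 14:03,40.43999,-3.68938,268.65655,Indoor,Rest,0.00893,2.3991
2017-03-24 14:03,2017-03-24 14:37,40.44,-3.689,347.06125,Outdoor,Walk,0.01326,4.60203
2017-03-24 14:37,2017-03-24 14:44,40.43999,-3.68938,28.72532,Indoor,Rest,0.00893,0.25652
2017-03-24 14:44,2017-03-24 14:59,40.44,-3.689,141.90761,Outdoor,Walk,0.01326,1.88169
2017-03-24 14:59,2017-03-24 15:58,40.43999,-3.68938,273.87957,Indoor,Rest,0.00893,2.44574
2017-03-24 15:58,2017-03-24 16:09,40.44,-3.689,80.2915,Outdoor,Walk,0.01326,1.06467
2017-03-24 16:09,2017-03-24 17:00,40.43999,-3.68938,275.25632,Indoor,Rest,0.00893,2.45804
2017-03-24 17:00,2017-03-24 17:12,40.44,-3.689,70.15613,Outdoor,Walk,0.01326,0.93027
2017-03-24 17:12,2017-03-24 17:41,40.43999,-3.68938,253.86892,Indoor,Rest,0.00893,2.26705
2017-03-24 17:41,2017-03-24 17:56,40.44,-3.689,63.02457,Outdoor,Walk,0.01326,0.83571
2017-03-24 17:56,2017-03-24 18:32,40.43999,-3.68938,278.09301,Indoor,Rest,0.00893,2.48337
2017-03-24 18:32,2017-03-24 18:46,40.44,-3.689,85.27723,Outdoor,Walk,0.01326,1.13078
2017-03-24 18:46,2017-03-24 19:19,40.43999,-3.68938,193.88363,Indoor,Rest,0.00893,1.73138
2017-03-24 19:52,2017-03-24 20:08,40.451,-3.699,182.9052,Outdoor,Transport,0.00893,1.63334
2017-03-24 20:08,2017-03-24 21:13,40.461,-3.709,626.14768,Outdoor,Rest,0.00893,5.5915
2017-03-24 21:13,2017-03-24 21:21,40.459,-3.711,68.61289,Outdoor,Walk,0.01326,0.90981
2017-03-24 21:21,2017-03-24 22:32,40.457,-3.712,414.90097,Outdoor,Rest,0.00893,3.70507
2017-03-24 22:32,2017-03-24 22:42,40.459,-3.711,51.34302,Outdoor,Walk,0.01326,0.68081
2017-03-24 22:42,2017-03-25 00:00,40.461,-3.709,6.56381,Outdoor,Rest,0.00893,0.05861
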