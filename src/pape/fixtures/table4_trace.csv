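Start Time,End Time,Latitude,Longitude,Activity
2017-03-24 00:00:00,2017-03-24 11:55:37,40.4612,-3.7093,Rest
2017-03-24 11:55:37,2017-03-24 11:59:20,40.4592,-3.7106,Walk
2017-03-24 11:59:20,2017-03-24 12:04:30,40.4571,-3.7118,Rest
2017-03-24 12:04:30,2017-03-24 12:23:44,40.4486,-3.7006,Transport
2017-03-24 12:23:44,2017-03-24 19:52:00,40.4400,-3.6894,Rest
2017-03-24 19:52:00,2017-03-24 20:08:40,40.4506,-3.6994,Transport
2017-03-24 20:08:40,2017-03-24 21:13:07,40.4612,-3.7093,Rest
2017-03-24 21:13:07,2017-03-24 21:21:55,40.4594,-3.7105,Walk
2017-03-24 21:21:55,2017-03-24 22:32:59,40.4575,-3.7117,Rest
2017-03-24 22:32:59,2017-03-24 22:42:51,40.4594,-3.7105,Walk
2017-03-24 22:42:51,2017-03-25 00:00:00,40.4612,-3.7093,Rest
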