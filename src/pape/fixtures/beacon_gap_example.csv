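beacon_id,datetime
B1,2017-03-24 14:37:46
B1,2017-03-24 14:38:46
B1,2017-03-24 14:39:46
B1,2017-03-24 14:40:46
B1,2017-03-24 14:41:46
B1,2017-03-24 14:42:46
B1,2017-03-24 14:43:46
B1,2017-03-24 14:44:59
B1,2017-03-24 14:59:00
B1,2017-03-24 15:00:00
B1,2017-03-24 15:01:00
B1,2017-03-24 15:02:00
B1,2017-03-24 15:03:00
B1,2017-03-24 15:04:00
B1,2017-03-24 15:05:00
B1,2017-03-24 15:06:00
B1,2017-03-24 15:07:00
B1,2017-03-24 15:08:00
B1,2017-03-24 15:09:00
B1,2017-03-24 15:10:00
B1,2017-03-24 15:11:00
B1,2017-03-24 15:12:00
B1,2017-03-24 15:13:00
B1,2017-03-24 15:14:00
B1,2017-03-24 15:15:00
B1,2017-03-24 15:16:00
B1,2017-03-24 15:17:00
B1,2017-03-24 15:18:00
B1,2017-03-24 15:19:00
B1,2017-03-24 15:20:00
B1,2017-03-24 15:21:00
B1,2017-03-24 15:22:00
B1,2017-03-24 15:23:00
B1,2017-03-24 15:24:00
B1,2017-03-24 15:25:00
B1,2017-03-24 15:26:00
B1,2017-03-24 15:27:00
B1,2017-03-24 15:28:00
B1,2017-03-24 15:29:00
B1,2017-03-24 15:30:00
B1,2017-03-24 15:31:00
B1,2017-03-24 15:32:00
B1,2017-03-24 15:33:00
B1,2017-03-24 15:34:00
B1,2017-03-24 15:35:00
B1,2017-03-24 15:36:00
B1,2017-03-24 15:37:00
B1,2017-03-24 15:38:00
B1,2017-03-24 15:39:00
B1,2017-03-24 15:40:00
B1,2017-03-24 15:41:00
B1,2017-03-24 15:42:00
B1,2017-03-24 15:43:00
B1,2017-03-24 15:44:00
B1,2017-03-24 15:45:00
B1,2017-03-24 15:46:00
B1,2017-03-24 15:47:00
B1,2017-03-24 15:48:00
B1,2017-03-24 15:49:00
B1,2017-03-24 15:50:00
B1,2017-03-24 15:51:00
B1,2017-03-24 15:52:00
B1,2017-03-24 15:53:00
B1,2017-03-24 15:54:00
B1,2017-03-24 15:55:00
B1,2017-03-24 15:56:00
B1,2017-03-24 15:57:00
B1,2017-03-24 15:58:00
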