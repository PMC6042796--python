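fiber,run,value
1,1,8.2
2,1,5.4
2,2,5.6
2,3,10.4
2,4,11.4
2,5,8.2
2,6,8.9
3,1,31.3
3,2,15.8
3,3,14.8
4,1,9.6
4,2,11.0
4,3,17.1
5,1,7.5
5,2,4.3
5,3,2.7
5,4,2.8
5,5,3.1
5,6,3.9
5,7,3.2
6,1,4.8
6,2,4.5
6,3,7.3
6,4,5.4
6,5,9.5
6,6,5.8
7,1,4.7
7,2,2.6
7,3,5.2
7,4,2.7
7,5,3.7
7,6,6.4
7,7,4.0
7,8,5.6
7,9,4.3
8,1,3.4
9,1,5.9
9,2,4.4
9,3,6.9
9,4,15.0
9,5,9.9
9,6,6.1
9,7,7.9
9,8,14.5
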