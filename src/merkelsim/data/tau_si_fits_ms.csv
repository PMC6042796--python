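fiber,run,value
1,1,163.7
1,2,555.6
1,3,288.2
1,4,387.6
2,1,42.8
2,2,50.3
2,3,342.5
2,4,30.0
2,5,43.0
3,1,7.2
3,2,4.0
3,3,7.9
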