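fiber,run,value
1,1,0.41
1,2,1.00
1,3,0.88
1,4,1.00
2,1,0.19
2,2,0.33
2,3,1.00
2,4,0.36
2,5,0.50
3,1,0.21
3,2,0.26
3,3,0.27
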