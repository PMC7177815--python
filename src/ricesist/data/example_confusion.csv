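,rice,forest,urban,water
rice,4089,136,73,13
forest,72,3008,31,3
urban,79,65,6272,26
water,6,2,8,3213
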