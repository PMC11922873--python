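code,label
MD,physician
PH,pharmacist
OT,other health-professional
HP,other health-professional
RN,other health-professional
CN,consumer
LW,lawyer
,unknown
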