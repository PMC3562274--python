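# Default blocklist of erroneously coded acute complications, removed before
# comorbidity mapping. The source method names the conditions, not the codes;
# the code spans below are this package's interpretation and are editable.
condition,spans
acute post-haemorrhagic anaemia,D62
acute subendocardial myocardial infarction,I21.4
acute renal failure,N17
acute respiratory infections,J00-J22
fever,R50
post-traumatic amnesia,R41.1
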