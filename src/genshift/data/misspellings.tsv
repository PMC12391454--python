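apendectmy	appendectomy
artroplsty	arthroplasty
bilatrl	bilateral
colecystectmy	cholecystectomy
fracure	fracture
laproscpic	laparoscopic
repalcemnt	replacement
rescton	resection
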