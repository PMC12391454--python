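acdf	anterior cervical discectomy fusion
alif	anterior lumbar interbody fusion
avr	aortic valve replacement
cabg	coronary artery bypass graft
cea	carotid endarterectomy
la	laparoscopic appendectomy
lc	laparoscopic cholecystectomy
lihr	laparoscopic inguinal hernia repair
mvr	mitral valve replacement
orif	open reduction internal fixation
pha	partial hip arthroplasty
plif	posterior lumbar interbody fusion
rsa	reverse shoulder arthroplasty
tha	total hip arthroplasty
tka	total knee arthroplasty
tsa	total shoulder arthroplasty
turp	transurethral resection prostate
uka	partial knee arthroplasty
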