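acetabular
adenoidectomy
allograft
anastomosis
and
anesthesia
aneurysm
angioplasty
ankle
annuloplasty
anterior
aortic
appendectomy
appendix
application
artery
arthrodesis
arthroplasty
assessment
assisted
bilateral
bioprosthetic
biopsy
bladder
breast
bypass
cage
cardiac
carotid
carpal
cataract
cautery
cervical
chest
cholangiogram
cholecystectomy
clamping
closed
colectomy
colon
complex
component
conduit
core
coronary
craniotomy
cuff
cystoscopy
decompression
defect
diagnostic
discectomy
diverting
drain
dural
eight
endarterectomy
endoscopic
endoscopy
exchange
excision
extraction
femoral
five
fixation
four
fracture
fusion
gallbladder
glenoid
graft
grafting
guidance
guided
hardware
hernia
herniorrhaphy
hilar
hip
implant
incision
inguinal
instrumentation
interbody
internal
irrigation
kidney
knee
laparoscopic
left
lens
liner
liver
lobectomy
localization
lower
lumbar
lung
mammary
management
mastectomy
median
mesh
mitral
monitoring
multiple
navigation
needle
nephrectomy
nerve
nine
node
nodule
one
open
ostomy
partial
patch
pedicle
percutaneous
perforated
phacoemulsification
placement
plate
poly
posterior
prevena
primary
prostate
prostatectomy
radical
recurrent
reduction
release
removal
repair
replacement
resection
revascularization
reverse
revision
right
ring
robotic
rotator
sampling
saphenous
screw
screws
sentinel
seven
shoulder
shunt
single
six
sparing
spine
splint
standard
stent
stone
system
ten
therapeutic
thoracoscopic
three
thyroid
thyroidectomy
tonsil
tonsillectomy
topical
total
transurethral
tube
tumor
tunnel
two
ultrasound
upper
valve
vein
wire
with
wrist
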