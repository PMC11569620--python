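good	0.75	0.0
great	0.75	0.0
happy	0.875	0.0
joy	0.875	0.0
love	0.75	0.0
loved	0.75	0.0
wonderful	0.75	0.0
beautiful	0.75	0.0
nice	0.625	0.0
sweet	0.625	0.0
calm	0.625	0.0
perfect	0.75	0.0
amazing	0.875	0.0
excited	0.75	0.0
exciting	0.75	0.0
glad	0.625	0.0
thankful	0.625	0.0
grateful	0.75	0.0
blessed	0.75	0.0
hope	0.5	0.125
hoping	0.5	0.125
hopeful	0.625	0.0
proud	0.625	0.0
cheerful	0.75	0.0
content	0.5	0.0
relief	0.625	0.125
relieved	0.625	0.0
relaxed	0.625	0.0
fun	0.625	0.0
laugh	0.625	0.0
laughed	0.625	0.0
smile	0.625	0.0
support	0.5	0.0
supportive	0.625	0.0
supported	0.5	0.0
helpful	0.5	0.0
kind	0.5	0.0
gentle	0.5	0.0
comfort	0.5	0.125
comfortable	0.5	0.0
cute	0.625	0.0
pretty	0.625	0.0
gorgeous	0.75	0.0
adorable	0.75	0.0
lovely	0.75	0.0
lucky	0.625	0.0
optimistic	0.75	0.0
positive	0.625	0.0
better	0.5	0.125
best	0.75	0.0
well	0.5	0.0
healthy	0.5	0.0
energetic	0.5	0.0
energy	0.375	0.0
strong	0.5	0.0
confident	0.625	0.0
ready	0.375	0.0
pampered	0.625	0.0
celebrate	0.625	0.0
treat	0.375	0.0
treated	0.375	0.0
enjoy	0.625	0.0
enjoyed	0.625	0.0
peaceful	0.625	0.0
delighted	0.875	0.0
satisfied	0.625	0.0
pleased	0.625	0.0
sad	0.0	0.75
unhappy	0.0	0.75
depressed	0.0	0.875
depressing	0.0	0.75
depression	0.0	0.75
miserable	0.0	0.875
terrible	0.0	0.75
horrible	0.0	0.875
awful	0.0	0.75
bad	0.0	0.625
worst	0.0	0.875
worse	0.0	0.625
worried	0.0	0.625
worry	0.0	0.625
worrying	0.0	0.625
worrisome	0.0	0.625
anxious	0.0	0.75
anxiety	0.0	0.75
nervous	0.0	0.625
afraid	0.0	0.75
scared	0.0	0.75
scary	0.0	0.625
fear	0.0	0.75
panic	0.0	0.75
panicked	0.0	0.75
stress	0.0	0.625
stressed	0.0	0.75
stressful	0.0	0.625
overwhelmed	0.0	0.75
overwhelming	0.0	0.625
exhausted	0.0	0.625
exhausting	0.0	0.625
tired	0.0	0.5
fatigue	0.0	0.5
drained	0.0	0.625
weary	0.0	0.5
angry	0.0	0.75
anger	0.0	0.75
mad	0.0	0.625
furious	0.0	0.875
annoyed	0.0	0.5
irritated	0.0	0.625
frustrated	0.0	0.625
frustrating	0.0	0.625
upset	0.0	0.625
hurt	0.0	0.625
hurts	0.0	0.625
pain	0.0	0.625
painful	0.0	0.75
ache	0.0	0.5
aching	0.0	0.5
sore	0.0	0.5
cramp	0.0	0.5
cramping	0.0	0.5
cramps	0.0	0.5
headache	0.0	0.5
migraine	0.0	0.625
nausea	0.0	0.5
nauseous	0.0	0.625
vomiting	0.0	0.625
sick	0.0	0.625
ill	0.0	0.625
crying	0.0	0.625
cried	0.0	0.625
cry	0.0	0.625
tears	0.0	0.5
lonely	0.0	0.75
alone	0.0	0.5
isolated	0.0	0.625
hopeless	0.0	0.875
helpless	0.0	0.75
worthless	0.0	0.875
guilty	0.0	0.625
guilt	0.0	0.625
shame	0.0	0.75
ashamed	0.0	0.75
numb	0.0	0.5
empty	0.0	0.5
dark	0.0	0.375
struggle	0.0	0.625
struggling	0.0	0.625
difficult	0.0	0.5
hard	0.0	0.375
rough	0.0	0.5
tough	0.0	0.375
crisis	0.0	0.75
emergency	0.0	0.625
danger	0.0	0.75
dangerous	0.0	0.75
risk	0.0	0.5
threat	0.0	0.625
loss	0.0	0.625
lost	0.0	0.5
losing	0.0	0.5
grief	0.0	0.875
grieving	0.0	0.875
death	0.0	0.75
dying	0.0	0.75
broke	0.0	0.5
debt	0.0	0.625
bills	0.0	0.375
unemployed	0.0	0.625
jobless	0.0	0.625
layoff	0.0	0.625
evicted	0.0	0.75
poor	0.0	0.625
crippling	0.0	0.75
suck	0.0	0.625
sucks	0.0	0.625
crap	0.0	0.625
damn	0.0	0.5
hate	0.0	0.875
hated	0.0	0.875
resent	0.0	0.75
resents	0.0	0.75
dread	0.0	0.75
insecure	0.0	0.625
doubt	0.0	0.5
uncertain	0.0	0.5
unsure	0.0	0.375
trouble	0.0	0.5
problem	0.0	0.5
problems	0.0	0.5
issue	0.0	0.375
issues	0.0	0.375
conflict	0.0	0.5
fight	0.0	0.625
fighting	0.0	0.625
argue	0.0	0.5
arguing	0.0	0.5
yelling	0.0	0.625
tension	0.0	0.5
swelling	0.0	0.375
swollen	0.0	0.375
dizzy	0.0	0.5
dizziness	0.0	0.5
fever	0.0	0.5
bleeding	0.0	0.625
blood	0.0	0.25
heartburn	0.0	0.375
insomnia	0.0	0.625
sleepless	0.0	0.625
mood	0.125	0.125
okay	0.25	0.0
fine	0.375	0.0
alright	0.25	0.0
baby	0.375	0.0
kick	0.25	0.0
kicky	0.375	0.0
ultrasound	0.25	0.0
home	0.125	0.0
family	0.25	0.0
friend	0.375	0.0
partner	0.25	0.0
husband	0.125	0.0
work	0.0	0.25
job	0.125	0.125
money	0.0	0.25
rent	0.0	0.25
mortgage	0.0	0.25
pay	0.125	0.125
therapist	0.125	0.25
therapy	0.125	0.25
counseling	0.125	0.25
psychiatrist	0.0	0.25
medication	0.0	0.25
meds	0.0	0.25
doctor	0.125	0.125
hospital	0.0	0.375
appointment	0.125	0.125
pregnant	0.25	0.0
pregnancy	0.25	0.0
contractions	0.0	0.375
doula	0.25	0.0
midwife	0.25	0.0
covid	0.0	0.5
pandemic	0.0	0.625
mask	0.0	0.25
booster	0.125	0.125
vaccine	0.125	0.125
quarantine	0.0	0.5
lockdown	0.0	0.625
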