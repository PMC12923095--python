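did	deed
in	inn
inn	in
heal	heel
heel	heal
pain	pane
pane	pain
week	weak
weak	week
sore	soar
soar	sore
vein	vain|vane
vain	vein|vane
waist	waste
waste	waist
see	sea
sea	see
hear	here
here	hear
right	write|rite
write	right|rite
rite	right|write
nose	knows
knows	nose
whole	hole
hole	whole
oral	aural
aural	oral
sight	site|cite
site	sight|cite
cite	site|sight
flu	flew|flue
flew	flu|flue
great	grate
grate	great
night	knight
knight	night
days	daze
daze	days
hours	ours
ours	hours
time	thyme
thyme	time
feet	feat
feat	feet
hair	hare
hare	hair
son	sun
sun	son
one	won
won	one
new	knew
knew	new
no	know
know	no
be	bee
bee	be
their	there
there	their
would	wood
wood	would
some	sum
sum	some
made	maid
maid	made
plain	plane
plane	plain
fair	fare
fare	fair
course	coarse
coarse	course
sole	soul
soul	sole
steel	steal
steal	steel
cell	sell
sell	cell
cells	sells
sells	cells
cereal	serial
serial	cereal
high	hi
weigh	way|whey
way	weigh|whey
weight	wait
wait	weight
read	reed
reed	read
bored	board
board	bored
allowed	aloud
aloud	allowed
seen	scene
scene	seen
ileum	ilium
ilium	ileum
humerus	humorous
humorous	humerus
mucus	mucous
mucous	mucus
callus	callous
callous	callus
gait	gate
gate	gait
vial	phial|vile
phial	vial|vile
palate	pallet|palette
pallet	palate|palette
palette	palate|pallet
dye	die
die	dye
patience	patients
patients	patience
red	read
to	too|two
too	to|two
two	to|too
for	four|fore
four	for|fore
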