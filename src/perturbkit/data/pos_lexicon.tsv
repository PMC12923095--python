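the	determiner
a	determiner
an	determiner
this	determiner
that	determiner
these	determiner
those	determiner
my	determiner
your	determiner
his	determiner
her	determiner
its	determiner
our	determiner
their	determiner
i	pronoun
you	pronoun
he	pronoun
she	pronoun
it	pronoun
we	pronoun
they	pronoun
me	pronoun
him	pronoun
them	pronoun
us	pronoun
who	pronoun
whom	pronoun
what	pronoun
which	pronoun
of	adposition
in	adposition
on	adposition
at	adposition
by	adposition
with	adposition
from	adposition
into	adposition
onto	adposition
over	adposition
under	adposition
about	adposition
after	adposition
before	adposition
between	adposition
during	adposition
through	adposition
to	adposition
for	adposition
and	conjunction
or	conjunction
but	conjunction
nor	conjunction
so	conjunction
yet	conjunction
if	conjunction
because	conjunction
while	conjunction
when	conjunction
where	conjunction
as	conjunction
than	conjunction
not	other
how	other
why	other
is	auxiliary
am	auxiliary
are	auxiliary
was	auxiliary
were	auxiliary
been	auxiliary
being	auxiliary
will	auxiliary
shall	auxiliary
should	auxiliary
can	auxiliary
could	auxiliary
may	auxiliary
might	auxiliary
must	auxiliary
would	auxiliary
be	auxiliary
do	verb
does	verb
did	verb
done	verb
have	verb
has	verb
had	verb
affect	verb
given	verb
see	verb
hear	verb
know	verb
knew	verb
write	verb
wait	verb
weigh	verb
steal	verb
soar	verb
read	verb
heal	verb
sell	verb
die	verb
dye	verb
made	verb
won	verb
felt	verb
said	verb
noted	verb
reported	verb
showed	verb
found	verb
gave	verb
took	verb
visited	verb
described	verb
recommended	verb
received	verb
improved	verb
worsened	verb
remains	verb
suggests	verb
predicts	verb
allowed	verb
seen	verb
life	noun
discharge	noun
summary	noun
quality	noun
pain	noun
pane	noun
week	noun
heel	noun
vein	noun
waist	noun
sea	noun
nose	noun
hole	noun
sight	noun
site	noun
flu	noun
night	noun
knight	noun
days	noun
hours	noun
time	noun
feet	noun
hair	noun
son	noun
sun	noun
cell	noun
cells	noun
cereal	noun
way	noun
weight	noun
board	noun
scene	noun
ileum	noun
ilium	noun
humerus	noun
mucus	noun
callus	noun
gait	noun
gate	noun
vial	noun
palate	noun
patients	noun
patience	noun
patient	noun
doctor	noun
nurse	noun
clinic	noun
hospital	noun
ward	noun
chart	noun
note	noun
fever	noun
rash	noun
cough	noun
dose	noun
tablet	noun
care	noun
visit	noun
course	noun
sole	noun
soul	noun
steel	noun
sum	noun
wood	noun
maid	noun
plane	noun
fare	noun
grate	noun
hare	noun
bee	noun
inn	noun
deed	noun
one	number
two	number
three	number
four	number
five	number
ten	number
weak	adjective
sore	adjective
whole	adjective
oral	adjective
aural	adjective
great	adjective
new	adjective
plain	adjective
fair	adjective
coarse	adjective
high	adjective
bored	adjective
humorous	adjective
mucous	adjective
callous	adjective
vain	adjective
red	adjective
overall	adjective
severe	adjective
mild	adjective
chronic	adjective
acute	adjective
stable	adjective
tired	adjective
happy	adjective
sad	adjective
calm	adjective
worried	adjective
some	determiner
no	determiner
very	adverb
quite	adverb
really	adverb
often	adverb
never	adverb
always	adverb
sometimes	adverb
soon	adverb
now	adverb
then	adverb
here	adverb
there	adverb
well	adverb
today	adverb
daily	adverb
twice	adverb
aloud	adverb
too	adverb
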