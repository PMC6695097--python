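# word	class	root
# Function (closed-class) words
the	function	the
a	function	a
an	function	an
he	function	he
she	function	she
it	function	it
they	function	they
we	function	we
you	function	you
i	function	i
his	function	his
her	function	her
their	function	their
its	function	its
our	function	our
your	function	your
to	function	to
on	function	on
in	function	in
at	function	at
with	function	with
and	function	and
of	function	of
for	function	for
from	function	from
by	function	by
can	function	can
could	function	could
will	function	will
would	function	would
this	function	this
that	function	that
these	function	these
those	function	those
there	function	there
not	function	not
no	function	no
some	function	some
any	function	any
but	function	but
or	function	or
as	function	as
if	function	if
so	function	so
up	function	up
out	function	out
into	function	into
over	function	over
under	function	under
off	function	off
down	function	down
has	function	has
have	function	have
had	function	had
do	function	do
does	function	does
did	function	did
# Forms of "to be" (kept apart from content matching)
be	be_form	be
am	be_form	am
is	be_form	is
are	be_form	are
was	be_form	was
were	be_form	were
been	be_form	been
being	be_form	being
# Content words from the worked examples
break	content	break
broke	content	break
breaks	content	break
leg	content	leg
legs	content	leg
daughter	content	daughter
daughters	content	daughter
set	content	set
sets	content	set
table	content	table
tables	content	table
go	content	go
went	content	go
goes	content	go
going	content	go
very	content	very
fast	content	fast
faster	content	fast
man	content	man
men	content	man
turn	content	turn
turns	content	turn
turned	content	turn
turning	content	turn
faucet	content	faucet
faucets	content	faucet
tree	content	tree
trees	content	tree
father	content	father
fathers	content	father
forget	content	forget
forgot	content	forget
forgets	content	forget
bread	content	bread
boy	content	boy
boys	content	boy
hurry	content	hurry
hurried	content	hurry
hurries	content	hurry
school	content	school
schools	content	school
bucket	content	bucket
buckets	content	bucket
hold	content	hold
holds	content	hold
held	content	hold
water	content	water
# Simulator target vocabulary: nouns (singular/plural pairs)
garden	content	garden
gardens	content	garden
kitten	content	kitten
kittens	content	kitten
farmer	content	farmer
farmers	content	farmer
ticket	content	ticket
tickets	content	ticket
carpet	content	carpet
carpets	content	carpet
candle	content	candle
candles	content	candle
pencil	content	pencil
pencils	content	pencil
sister	content	sister
sisters	content	sister
# Simulator target vocabulary: verbs (base/past pairs)
carry	content	carry
carried	content	carry
clean	content	clean
cleaned	content	clean
paint	content	paint
painted	content	paint
find	content	find
found	content	find
wash	content	wash
washed	content	wash
open	content	open
opened	content	open
close	content	close
closed	content	close
fill	content	fill
filled	content	fill
move	content	move
moved	content	move
# Simulator target vocabulary: adjectives (base/comparative pairs)
old	content	old
older	content	old
young	content	young
younger	content	young
green	content	green
greener	content	green
sweet	content	sweet
sweeter	content	sweet
warm	content	warm
warmer	content	warm
cold	content	cold
colder	content	cold
# Masker-talker vocabulary (disjoint from target content words)
window	content	window
windows	content	window
mountain	content	mountain
mountains	content	mountain
river	content	river
rivers	content	river
doctor	content	doctor
doctors	content	doctor
letter	content	letter
letters	content	letter
summer	content	summer
summers	content	summer
market	content	market
markets	content	market
dinner	content	dinner
dinners	content	dinner
jacket	content	jacket
jackets	content	jacket
puppy	content	puppy
puppies	content	puppy
watch	content	watch
watched	content	watch
visit	content	visit
visited	content	visit
borrow	content	borrow
borrowed	content	borrow
follow	content	follow
followed	content	follow
answer	content	answer
answered	content	answer
listen	content	listen
listened	content	listen
# Decoy vocabulary (disjoint from target and masker content words)
unicorn	content	unicorn
wizard	content	wizard
planet	content	planet
robot	content	robot
dragon	content	dragon
pirate	content	pirate
castle	content	castle
rocket	content	rocket
jump	content	jump
whistle	content	whistle
gallop	content	gallop
vanish	content	vanish
sparkle	content	sparkle
wander	content	wander
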