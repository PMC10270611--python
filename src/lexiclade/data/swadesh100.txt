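I
you
we
this
that
who
what
not
all
many
one
two
big
long
small
woman
man
person
fish
bird
dog
louse
tree
seed
leaf
root
bark
skin
flesh
blood
bone
grease
egg
horn
tail
feather
hair
head
ear
eye
nose
mouth
tooth
tongue
claw
foot
knee
hand
belly
neck
breast
heart
liver
drink
eat
bite
see
hear
know
sleep
die
kill
swim
fly
walk
come
lie
sit
stand
give
say
sun
moon
star
water
rain
stone
sand
earth
cloud
smoke
fire
ash
burn
path
mountain
red
green
yellow
white
black
night
hot
cold
full
new
good
round
dry
name
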