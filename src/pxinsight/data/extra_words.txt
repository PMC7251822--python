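always
answered
arrived
asked
back
badly
brought
called
came
changed
cleaned
closed
come
coming
day
days
done
early
enough
everything
explained
feel
feeling
felt
first
gave
get
getting
give
given
go
going
gone
got
happened
hard
hardly
hear
heard
helped
kept
knew
know
left
listened
long
looked
lot
made
make
many
much
needed
nothing
often
one
opened
quickly
received
said
sat
saw
say
seemed
seen
several
slept
slowly
someone
something
sometimes
soon
spoke
spoken
stayed
still
take
taken
talked
think
thought
times
told
took
treated
tried
twice
waited
walked
want
wanted
well
went
without
woke
worked
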