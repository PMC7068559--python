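# Open English personal-pronoun list (replaces proprietary category
# dictionaries; substitute your own licensed list via configuration).
i
me
my
mine
myself
we
us
our
ours
ourselves
you
your
yours
yourself
yourselves
he
him
his
himself
she
her
hers
herself
it
its
itself
they
them
their
theirs
themselves
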