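# English stop words, v1
a
about
above
after
again
against
all
also
among
an
and
any
are
as
at
base
based
be
because
been
before
being
below
between
both
but
by
can
cannot
case
cases
cell
cells
compared
control
could
data
day
days
did
do
does
done
dose
doses
down
during
each
effect
effects
enzyme
enzymes
exposure
few
first
for
from
further
group
groups
had
has
have
here
high
higher
how
however
in
increase
increased
increases
into
is
it
its
latter
level
levels
low
lower
may
measured
model
more
most
new
no
nor
not
observed
of
off
on
once
only
or
other
our
out
over
own
patient
patients
per
present
protein
proteins
rate
results
same
sample
samples
second
serum
should
showed
shown
significant
significantly
so
some
study
such
test
than
that
the
their
then
there
these
they
this
those
through
time
to
treated
treatment
two
under
until
up
upon
using
value
values
very
was
water
we
were
what
when
where
which
while
who
why
will
with
within
without
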