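a
an
and
are
as
at
be
but
by
for
from
in
into
is
it
of
on
or
over
p
post
pre
s
status
that
the
this
to
under
was
were
with
without
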