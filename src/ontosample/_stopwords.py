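"""Default English stop-word list for the annotation pipeline (~130 words).

A compact list of function words that carry no concept information in sample
metadata; matching can optionally skip these in both the text and the
dictionary variants.
"""

DEFAULT_STOPWORDS = frozenset("""
a about above after again against all am an and any are as at be because
been before being below between both but by can cannot could did do does
doing down during each few for from further had has have having he her here
hers herself him himself his how i if in into is it its itself just me more
most my myself no nor not now of off on once only or other our ours
ourselves out over own same she should so some such than that the their
theirs them themselves then there these they this those through to too under
until up very was we were what when where which while who whom why will with
would you your yours yourself yourselves
""".split())
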