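"""Governing verbs and relating words on a dependency tree.

Uses the hand-encoded worked-example tree: a sentence about acetaminophen
and anaphylaxis where the disease hangs under "produce" and the chemical
under "demonstrated".
"""

from religator import figure_tree_fixture, governing_verb, relating_word

parse, chem, dis = figure_tree_fixture()
print("sentence:", " ".join(t.word for t in parse.tokens))

gov_dis = governing_verb(parse, dis)
gov_chem = governing_verb(parse, chem)
rw = relating_word(parse, chem, dis)
print(f"governing verb of {parse.token(dis).word!r}: {parse.token(gov_dis).word!r}")
print(f"governing verb of {parse.token(chem).word!r}: {parse.token(gov_chem).word!r}")
print(f"relating word of the pair: {parse.token(rw).word!r}")
# The governing verb is the first verb met walking from a token towards the
# root; the relating word is the pair's lowest common ancestor.  Here the
# chemical's governing verb ("demonstrated") is also the relating word —
# exactly the configuration the identity features detect.
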