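"""Reading and summarizing a PubTator corpus.

Writes a tiny two-document corpus, reads it back, and prints its summary
statistics: document/mention counts, unique MeSH identifiers, and the number
of document-level chemical-induced-disease relations.
"""

import tempfile
from pathlib import Path

from religator import corpus_stats, read_pubtator

CONTENT = """\
1001|t|Aspirin study
1001|a|Aspirin induced asthma.
1001\t0\t7\tAspirin\tChemical\tD001241
1001\t14\t21\tAspirin\tChemical\tD001241
1001\t30\t36\tasthma\tDisease\tD001249
1001\tCID\tD001241\tD001249

1002|t|Case report
1002|a|Nausea after naproxen and ibuprofen dosing.
1002\t12\t18\tNausea\tDisease\tD009325
1002\t25\t33\tnaproxen\tChemical\tD009288
1002\t38\t47\tibuprofen\tChemical\tD007052|D015257
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "corpus.pubtator"
    path.write_text(CONTENT, encoding="utf-8")
    corpus = read_pubtator(path)

doc = corpus.documents[0]
print(f"document {doc.doc_id}: {len(doc.mentions)} mentions, "
      f"{len(doc.relations)} relation(s)")
print(f"  first mention slices to {doc.text[0:7]!r} (offset invariant)")

stats = corpus_stats(corpus)
print(f"corpus: {stats.documents} documents, "
      f"{stats.chemical_mentions} chemical / {stats.disease_mentions} disease mentions, "
      f"{stats.unique_chemical_ids} / {stats.unique_disease_ids} unique ids, "
      f"{stats.relations} relations")
# Unique ids expand composite annotations (ibuprofen carries two MeSH ids),
# so three distinct chemicals yield four unique chemical identifiers.
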