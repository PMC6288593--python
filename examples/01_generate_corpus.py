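"""Generate a small synthetic ADE corpus and summarize it.

The generator emits clinical-style notes with gold entity spans (9 types)
and relations (7 types), a configurable SSLIF:ADE imbalance and a fraction
of relations crossing sentence boundaries.  The stats table shows the
realized per-type counts and the relation sentence-gap histogram.
"""

from adex.synthetic import GenConfig, corpus_stats, generate_corpus

cfg = GenConfig(n_train=50, n_test=10, seed=13)
corpus = generate_corpus(cfg)

doc = corpus.train[0]
print("--- first document -------------------------------------------")
print(doc.text)
print("entities:", [(e.etype, e.text) for e in doc.entities[:6]], "...")
print("relations:", [(r.rtype, r.arg1, r.arg2) for r in doc.relations[:4]])

stats = corpus_stats(corpus.train)
print("--- corpus statistics (train) --------------------------------")
for etype, n in sorted(stats["entities"].items(), key=lambda kv: -kv[1]):
    print(f"  {etype:<12} {n:>5}")
ratio = stats["entities"]["SSLIF"] / stats["entities"]["ADE"]
print(f"SSLIF:ADE imbalance ratio = {ratio:.1f} (configured ≈ 10)")
print("relation sentence-gap histogram:", stats["gap_histogram"])
print("(gap 0 = same sentence; gaps ≥ 1 are inter-sentence relations)")
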