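"""Independent brute-force oracles the implementation is checked against.

These deliberately share no code with the library paths they verify:
candidate selection is a double loop over catalog x ortholog rows, and
combination extraction is a windowed co-occurrence scan over token
indices around every cue match.
"""

from __future__ import annotations

import re


def intersection_oracle(pairs, catalog, id_map, threshold):
    """Double-loop set intersection: (symbol, human, dog, similarity) tuples.

    Assumes one ortholog row per human gene (the random tables the tests
    build satisfy this).
    """
    out = set()
    for symbol, entrez in catalog:
        human = id_map.get(entrez)
        if human is None:
            continue
        for p in pairs:
            if p.human_gene_id == human and p.similarity >= threshold:
                out.add((symbol, p.human_gene_id, p.dog_gene_id, p.similarity))
    return out


def windowed_cooccurrence_oracle(corpus, mentions_by_article, cue_rules, window):
    """All drug pairs co-occurring within 2*window tokens of a cue match.

    Returns {(article_id, frozenset({a, b}))} with names taken verbatim
    from the mention surfaces.  Token distance is measured on the same
    punctuation-keeping tokenization the extractor documents as its
    window unit.
    """
    from crossmine.text_prep import tokenize

    found = set()
    for article in corpus:
        text = article.text
        tokens = tokenize(text, keep_punct=True)
        mentions = mentions_by_article.get(article.article_id, [])

        def token_range(start, end):
            idx = [i for i, t in enumerate(tokens) if t.end > start and t.start < end]
            return (idx[0], idx[-1]) if idx else None

        for rule in cue_rules:
            for m in re.finditer(rule.pattern, text):
                cue = token_range(m.start(), m.end())
                if cue is None:
                    continue
                lo = cue[0] - 2 * window
                hi = cue[1] + 2 * window
                names = {}
                for ment in mentions:
                    r = token_range(ment.start, ment.end)
                    if r is not None and r[1] >= lo and r[0] <= hi:
                        names.setdefault(ment.surface.casefold(), ment.surface)
                drugs = sorted(names.values())
                for i in range(len(drugs)):
                    for j in range(i + 1, len(drugs)):
                        found.add(
                            (article.article_id, frozenset({drugs[i], drugs[j]}))
                        )
    return found
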