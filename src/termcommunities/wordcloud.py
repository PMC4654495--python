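"""Word-cloud specifications for term groups.

A community (or branch) is summarized by the words of its member term
names.  Each word's display size encodes its statistical enrichment in
the group relative to the full vocabulary of all term names (upper-tail
hypergeometric over token occurrences), and its color encodes which of
the three ontology domains its occurrences come from: BP maps to
yellow, MF to cyan, CC to magenta, mixing subtractively so an evenly
cross-domain word renders black.  The output is a data specification
(word, counts, p, size score, rgb), not a rendered image.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from scipy.stats import hypergeom

from .ontology_io import Ontology, TermRecord

__all__ = ["WordStat", "WordCloudSpec", "tokenize_names", "word_enrichment",
           "word_color", "build_wordcloud_spec"]

#: Split on whitespace, commas, slashes, parentheses, brackets and colons;
#: internal hyphens are preserved ("nucleotide-excision" stays one token).
_SPLIT_RE = re.compile(r"[\s,/():\[\]]+")

#: p-values are floored here before taking -log10.
P_FLOOR = 1e-300


@dataclass(frozen=True)
class WordStat:
    word: str
    count_in_group: int
    count_background: int
    p_enrich: float
    size_score: float
    domain_fractions: dict[str, float]
    rgb: tuple[float, float, float]


@dataclass
class WordCloudSpec:
    group_id: str
    words: list[WordStat]
    settings: dict = field(default_factory=dict)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("word\tcount\tbackground\tp\tsize_score\tr\tg\tb\n")
            for w in self.words:
                fh.write(
                    f"{w.word}\t{w.count_in_group}\t{w.count_background}\t"
                    f"{w.p_enrich!r}\t{w.size_score!r}\t"
                    f"{w.rgb[0]!r}\t{w.rgb[1]!r}\t{w.rgb[2]!r}\n"
                )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "group_id": self.group_id,
            "settings": self.settings,
            "words": [
                {"word": w.word, "count": w.count_in_group,
                 "background": w.count_background, "p": w.p_enrich,
                 "size_score": w.size_score,
                 "domain_fractions": w.domain_fractions, "rgb": list(w.rgb)}
                for w in self.words
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def tokenize_names(
    terms: list[TermRecord],
    min_length: int = 2,
    stopwords: set[str] | None = None,
) -> Counter:
    """Multiset of (token, namespace) occurrences over term names.

    Names are lowercased and split on whitespace and light punctuation;
    tokens shorter than ``min_length`` characters are dropped.  No
    stopword list is applied unless one is supplied.
    """
    stopwords = stopwords or set()
    counts: Counter = Counter()
    for rec in terms:
        for token in _SPLIT_RE.split(rec.name.lower()):
            token = token.strip("-.;'\"")
            if len(token) < min_length or token in stopwords:
                continue
            counts[(token, rec.namespace)] += 1
    return counts


def word_enrichment(
    group_tokens: Counter, background_tokens: Counter
) -> dict[str, float]:
    """Upper-tail hypergeometric p-value per word.

    The urn holds all N background token occurrences, K_w of them being
    word w; the group draws n tokens; p = P(X >= k_w observed).
    """
    group_words = _word_counts(group_tokens)
    bg_words = _word_counts(background_tokens)
    n = sum(group_tokens.values())
    N = sum(background_tokens.values())
    p: dict[str, float] = {}
    for word, k in group_words.items():
        K = bg_words.get(word, 0)
        if K < k:
            raise ValueError(
                f"word {word!r} occurs {k}x in the group but only {K}x in the "
                "background; tokenization settings are inconsistent"
            )
        # P(X >= k) = survival function at k-1
        p[word] = float(hypergeom.sf(k - 1, N, K, n))
    return p


def _word_counts(tokens: Counter) -> dict[str, int]:
    out: dict[str, int] = {}
    for (word, _ns), c in tokens.items():
        out[word] = out.get(word, 0) + c
    return out


def word_color(
    domain_occurrences: dict[str, int],
    domain_background: dict[str, int],
) -> tuple[float, float, float]:
    """Subtractive CMY color from normalized per-domain occurrence rates.

    Each domain's rate is occurrences divided by that domain's background
    occurrences (so the dominant overall domain does not wash out the
    others); rates are rescaled so the maximum is 1 and mapped through
    Y=BP, C=MF, M=CC.  A single-domain word is a pure primary; equal
    normalized rates give black.
    """
    if sum(domain_occurrences.values()) <= 0:
        raise ValueError("word has no occurrences")
    rates = {}
    for d in ("BP", "MF", "CC"):
        occ = domain_occurrences.get(d, 0)
        if occ > 0 and domain_background.get(d, 0) <= 0:
            raise ValueError(f"domain {d} has occurrences but empty background")
        bg = domain_background.get(d, 0)
        rates[d] = occ / bg if bg > 0 else 0.0
    peak = max(rates.values())
    scaled = {d: rates[d] / peak for d in rates}
    yellow, cyan, magenta = scaled["BP"], scaled["MF"], scaled["CC"]
    return (1.0 - cyan, 1.0 - magenta, 1.0 - yellow)


def build_wordcloud_spec(
    group: frozenset[str],
    ontology: Ontology,
    min_length: int = 2,
    stopwords: set[str] | None = None,
    top_k: int | None = None,
    group_id: str = "group",
) -> WordCloudSpec:
    """Tokenize, test enrichment and color every word of a term group.

    The background is the vocabulary of all non-obsolete term names in
    the ontology (all three domains).  Words are ordered by descending
    size score (-log10 p), ties by descending group count then word.
    """
    if not group:
        raise ValueError("term group is empty")
    members = [ontology.terms[t] for t in group
               if not ontology.terms[t].obsolete]
    background_terms = [ontology.terms[t] for t in ontology.active_terms()]
    group_tokens = tokenize_names(members, min_length=min_length,
                                  stopwords=stopwords)
    bg_tokens = tokenize_names(background_terms, min_length=min_length,
                               stopwords=stopwords)
    p_values = word_enrichment(group_tokens, bg_tokens)

    group_words = _word_counts(group_tokens)
    bg_words = _word_counts(bg_tokens)
    bg_domain_totals: dict[str, dict[str, int]] = {}
    for (word, ns), c in bg_tokens.items():
        bg_domain_totals.setdefault(word, {}).setdefault(ns, 0)
        bg_domain_totals[word][ns] += c

    import math

    stats = []
    for word, k in group_words.items():
        occ = {ns: c for (w, ns), c in group_tokens.items() if w == word}
        rgb = word_color(occ, bg_domain_totals[word])
        total = sum(occ.values())
        p = p_values[word]
        stats.append(WordStat(
            word=word,
            count_in_group=k,
            count_background=bg_words[word],
            p_enrich=p,
            size_score=-math.log10(max(p, P_FLOOR)),
            domain_fractions={ns: c / total for ns, c in sorted(occ.items())},
            rgb=rgb,
        ))
    stats.sort(key=lambda s: (-s.size_score, -s.count_in_group, s.word))
    if top_k is not None:
        stats = stats[:top_k]
    return WordCloudSpec(
        group_id=group_id,
        words=stats,
        settings={
            "min_length": min_length,
            "stopwords": sorted(stopwords) if stopwords else [],
            "split_pattern": _SPLIT_RE.pattern,
            "background": "all non-obsolete term names",
        },
    )
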