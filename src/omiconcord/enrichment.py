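"""Gene-set over-representation: Fisher exact upper tail and the EASE score.

Given a list of differentially regulated identifiers, a term with K members
in a background population of N identifiers, and an overlap of k out of the
n submitted identifiers, the enrichment p-value is the hypergeometric upper
tail P(X >= k). The EASE score is its conservative modification: one member
is removed from the observed overlap before taking the tail, i.e.
``ease_score(k) = fisher_exact_upper_tail(k - 1)``, which penalises terms
supported by very few overlapping identifiers. The background population
defaults to the set of identifiers detected in the experiment rather than
the whole genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom


@dataclass
class GeneSetCollection:
    """Named terms mapping to member-identifier sets over a background
    population. The population defaults to the union of all members."""

    terms: dict[str, set[str]]
    population: set[str] = field(default_factory=set)
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.population:
            self.population = set().union(*self.terms.values()) if self.terms else set()
        for term, members in self.terms.items():
            if not members:
                raise ValueError(f"term {term!r} is empty")
            stray = members - self.population
            if stray:
                raise ValueError(
                    f"term {term!r} has members outside the population: {sorted(stray)[:5]}"
                )

    @classmethod
    def from_gmt(cls, path, population: set[str] | None = None) -> "GeneSetCollection":
        terms: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    continue
                term, description, *members = fields
                terms[term] = {m for m in members if m}
                names[term] = description
        return cls(terms, population or set(), names)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for term in sorted(self.terms):
                members = "\t".join(sorted(self.terms[term]))
                fh.write(f"{term}\t{self.names.get(term, term)}\t{members}\n")


def _validate_counts(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"overlap k={k} outside [0, min(n={n}, K={K})]")
    if n > N or K > N:
        raise ValueError(f"list size n={n} and term size K={K} must not exceed N={N}")
    if min(n, K, N) < 0:
        raise ValueError("counts must be non-negative")


def fisher_exact_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n): the one-sided Fisher exact
    enrichment p-value."""
    _validate_counts(k, n, K, N)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def ease_score(k: int, n: int, K: int, N: int) -> float:
    """The EASE modification: the Fisher upper tail after removing one
    identifier from the observed overlap; always >= the plain Fisher p."""
    _validate_counts(k, n, K, N)
    return fisher_exact_upper_tail(max(k - 1, 0), n, K, N)


def annotation_chart(
    diff_ids, collection: GeneSetCollection, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Per-term enrichment of a differential identifier list.

    Identifiers outside the background population are dropped with a warning.
    Terms with zero overlap are omitted; records are sorted by EASE score
    ascending (ties by term id) and flagged ``enriched`` below the threshold.
    """
    diff_ids = set(diff_ids)
    stray = diff_ids - collection.population
    if stray:
        warnings.warn(f"dropping {len(stray)} identifiers outside the population")
        diff_ids -= stray
    if not diff_ids:
        warnings.warn("empty differential identifier list; no enrichment computed")
    N = len(collection.population)
    n = len(diff_ids)
    rows = []
    for term, members in collection.terms.items():
        k = len(diff_ids & members)
        if k < 1:
            continue
        K = len(members)
        fisher_p = fisher_exact_upper_tail(k, n, K, N)
        ease_p = ease_score(k, n, K, N)
        rows.append(
            (term, collection.names.get(term, term), k, n, K, N, fisher_p, ease_p)
        )
    chart = pd.DataFrame(
        rows, columns=["term", "name", "k", "n", "K", "N", "fisher_p", "ease_p"]
    ).sort_values(["ease_p", "term"], kind="mergesort", ignore_index=True)
    chart["enriched"] = chart["ease_p"] < p_threshold
    return chart
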