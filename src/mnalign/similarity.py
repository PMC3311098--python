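"""Similarity-score construction and topology-aware preprocessing.

Two standard score sources are supported: normalized BLAST bit scores
(``nBLAST``, the bit score of a pair divided by the geometric mean of the
two self bit scores, length-independent in [0, 1]) and Pfam-domain scores
(the sum of ``-ln PV`` over shared domains, using the per-protein domain
p-values).

The preprocessing step folds one hop of network topology into the
similarity matrix: for every cross-network pair with a positive score, it
greedily pairs up the two proteins' neighbors by descending similarity and
adds the summed neighbor similarity as an *extra* score, capped at the
original score so topology can at most double a pair's score.
"""

from __future__ import annotations

import math

from .core import (
    InputFormatError,
    NetworkCollection,
    SimilarityMatrix,
)

# protein -> {domain -> Pfam p-value in (0, 1]}
DomainPValueTable = dict[str, dict[str, float]]


def normalize_blast(raw_xy: float, raw_xx: float, raw_yy: float) -> float:
    """Normalized BLAST bit score: raw_xy / sqrt(raw_xx * raw_yy).

    The self scores must be positive (a protein always hits itself);
    the result is 1 for a self comparison and 0 for a missing hit.
    """
    if raw_xx <= 0 or raw_yy <= 0:
        raise InputFormatError(
            f"self bit scores must be positive, got ({raw_xx}, {raw_yy})"
        )
    if raw_xy < 0:
        raise InputFormatError(f"negative bit score {raw_xy}")
    return raw_xy / math.sqrt(raw_xx * raw_yy)


def domain_similarity(
    va: str, vb: str, table: DomainPValueTable
) -> float:
    """Domain-based similarity: sum of -ln PV(va, d) - ln PV(vb, d)
    over the shared domains d.  Zero when no domain is shared."""
    da = table.get(va, {})
    db = table.get(vb, {})
    total = 0.0
    for d in da.keys() & db.keys():
        for pv in (da[d], db[d]):
            if not 0 < pv <= 1:
                raise InputFormatError(
                    f"domain p-value {pv} outside (0, 1] for domain {d!r}"
                )
            total -= math.log(pv)
    return total


def greedy_neighbor_extra(
    va: str,
    vb: str,
    nets: NetworkCollection,
    sim: SimilarityMatrix,
) -> float:
    """Greedy one-hop neighbor-matching score for a cross-network pair.

    Repeatedly select the highest-similarity pair (va', vb') with va' a
    neighbor of va and vb' a neighbor of vb, neither selected before, and
    accumulate sim(va', vb') until either neighbor set is exhausted.
    Zero-similarity neighbor pairs contribute nothing and are skipped.
    Ties are broken on the lexicographically smallest unordered pair, which
    makes the result symmetric in (va, vb).
    """
    na = nets.neighbors(va)
    nb = nets.neighbors(vb)
    if not na or not nb:
        return 0.0
    candidates: list[tuple[float, str, str, str, str]] = []
    for x in na:
        partners = sim.partners(x)
        for y in nb:
            s = partners.get(y, 0.0)
            if s > 0.0:
                lo, hi = (x, y) if x <= y else (y, x)
                candidates.append((s, lo, hi, x, y))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    extra = 0.0
    for s, _, _, x, y in candidates:
        if x in used_a or y in used_b:
            continue
        extra += s
        used_a.add(x)
        used_b.add(y)
        if len(used_a) == len(na) or len(used_b) == len(nb):
            break
    return extra


def preprocess_similarity(
    nets: NetworkCollection, sim: SimilarityMatrix
) -> SimilarityMatrix:
    """Return a new matrix with the capped neighbor extra score added.

    For every stored pair: new = original + min(extra, original), where
    extra is :func:`greedy_neighbor_extra` computed from the *original*
    scores only.  Pairs with no stored score stay at 0 (the cap rule makes
    them unable to gain), so the support of the matrix is unchanged and
    every score lies in [original, 2 * original].
    """
    out: dict[tuple[str, str], float] = {}
    for a, b, s in sim.items():
        extra = greedy_neighbor_extra(a, b, nets, sim)
        out[(a, b)] = s + min(extra, s)
    return SimilarityMatrix(out)
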