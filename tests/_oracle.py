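"""Independent brute-force scorer used to cross-check the matcher.

Deliberately shares no code with the package: character counting by
``str.count``, and all argmax/argmin comparisons done in exact integer
arithmetic (cross-multiplied squared dot products, squared distances), so the
oracle has no floating-point path at all. Ties are exact.
"""

_SCHEME = "abcdefghijklmnopqrstuvwxyz-_+"


def counts(text):
    return [text.count(c) for c in _SCHEME]


def _dot(u, v):
    return sum(a * b for a, b in zip(u, v))


def _sq(v):
    return sum(a * a for a in v)


def _sqdist(u, v):
    return sum((a - b) ** 2 for a, b in zip(u, v))


def _cos_cmp(u, a, b):
    """Sign of cos(u,a) - cos(u,b), exactly (dots are nonnegative)."""
    da, db = _dot(u, a), _dot(u, b)
    lhs = da * da * _sq(b)
    rhs = db * db * _sq(a)
    return (lhs > rhs) - (lhs < rhs)


def brute_match(text, candidates, method):
    """Return the winning candidate label, or None for zero-vector/full tie.

    ``candidates`` is a list of (label, comparison_string) pairs. Semantics:
    cosine -> first label of maximal cosine; euclidean -> first label of
    minimal distance; hybrid -> unique cosine argmax, Euclidean deciding
    among exact cosine ties, None if still tied.
    """
    u = counts(text)
    if not any(u):
        return None
    vecs = [(label, counts(comp)) for label, comp in candidates]

    if method == "cosine":
        best = vecs[0]
        for cand in vecs[1:]:
            if _cos_cmp(u, cand[1], best[1]) > 0:
                best = cand
        return best[0]

    if method == "euclidean":
        best = vecs[0]
        for cand in vecs[1:]:
            if _sqdist(u, cand[1]) < _sqdist(u, best[1]):
                best = cand
        return best[0]

    assert method == "hybrid"
    tied = [vecs[0]]
    for cand in vecs[1:]:
        c = _cos_cmp(u, cand[1], tied[0][1])
        if c > 0:
            tied = [cand]
        elif c == 0:
            tied.append(cand)
    if len(tied) == 1:
        return tied[0][0]
    dmin = min(_sqdist(u, v) for _, v in tied)
    winners = [label for label, v in tied if _sqdist(u, v) == dmin]
    return winners[0] if len(winners) == 1 else None
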