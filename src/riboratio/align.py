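"""Pairwise sequence comparison primitives.

Both functions are backed by edlib, which computes exact unit-cost edit
alignments in C. One identity convention is used everywhere in the package
(greedy OTU clustering, read mapping, ZOTU-to-OTU mapping): take an optimal
edit alignment of the two full sequences, discard terminal gap columns, and
report matches divided by the remaining alignment columns. End gaps therefore
do not count against identity, which is the usual convention for amplicons of
slightly unequal length.
"""

from __future__ import annotations

import re

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def levenshtein(a: str, b: str, max_dist: int | None = None) -> int:
    """Unit-cost edit distance between two nucleotide strings.

    With ``max_dist`` set, distances larger than the bound are reported as
    ``max_dist + 1`` (the exact value is not resolved beyond the bound).
    """
    if a == b:
        return 0
    k = -1 if max_dist is None else int(max_dist)
    d = edlib.align(a, b, mode="NW", k=k)["editDistance"]
    if d == -1:
        return int(max_dist) + 1
    return d


def pairwise_identity(a: str, b: str, max_dist: int | None = None) -> float:
    """Fractional identity of two sequences in [0, 1].

    Identity is matches / alignment columns, terminal gap columns excluded,
    over an optimal unit-cost edit alignment. ``max_dist`` is an optional
    screening bound: pairs whose edit distance exceeds it return 0.0 without
    resolving the alignment (used by threshold-based callers, where any pair
    beyond the bound is below the identity threshold anyway).

    Raises ``ValueError`` on empty input.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if a == b:
        return 1.0
    if (len(b), b) < (len(a), a):
        a, b = b, a  # canonical order: ties among optimal alignments can
        # otherwise resolve differently per direction, breaking symmetry
    k = -1 if max_dist is None else int(max_dist)
    result = edlib.align(a, b, mode="NW", task="path", k=k)
    if result["editDistance"] == -1:
        return 0.0
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(result["cigar"])]
    # drop terminal indel runs so end gaps are free
    start, end = 0, len(ops)
    while start < end and ops[start][1] in "ID":
        start += 1
    while end > start and ops[end - 1][1] in "ID":
        end -= 1
    ops = ops[start:end]
    columns = sum(n for n, _ in ops)
    if columns == 0:
        return 0.0
    matches = sum(n for n, op in ops if op == "=")
    return matches / columns


def max_edits_for_identity(len_a: int, len_b: int, min_identity: float) -> int:
    """Edit-distance screening bound guaranteeing identity >= min_identity is kept.

    An alignment with ``d`` internal edits over ``c`` columns has identity
    ``1 - d/c``; terminal gaps (up to the length difference) are free for
    identity but still count toward the edit distance, so the bound adds the
    length difference plus a couple of slack edits for gap-inflated column
    counts.
    """
    longer = max(len_a, len_b)
    return abs(len_a - len_b) + int((1.0 - min_identity) * longer) + 2
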