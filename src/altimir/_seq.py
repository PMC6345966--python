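"""Low-level sequence utilities shared across modules.

The internal alphabet is uppercase DNA (``A C G T N``); RNA input is
converted at the boundary (``U`` -> ``T``) and converted back only in
reports where the field convention is RNA (mature miRNA sequences,
3' tails).
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


def unify(seq: str) -> str:
    """Uppercase and map U->T so DNA and RNA records compare equal."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    return s


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def occurrences(needle: str, haystack: str) -> list[int]:
    """All start offsets of exact occurrences of *needle* in *haystack*."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def approx_occurrences(needle: str, haystack: str, max_mismatch: int) -> list[int]:
    """Ungapped occurrences allowing up to *max_mismatch* substitutions."""
    if max_mismatch <= 0:
        return occurrences(needle, haystack)
    n, m = len(needle), len(haystack)
    out = []
    for i in range(m - n + 1):
        mm = 0
        for a, b in zip(needle, haystack[i : i + n]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            out.append(i)
    return out
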