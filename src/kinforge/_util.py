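"""Small shared helpers: natural sorting, string normalization, Jaro-Winkler."""

from __future__ import annotations

import re
import unicodedata

_NAT_SPLIT = re.compile(r"(\d+)")


def natural_key(s: str):
    """Sort key splitting digit runs so @I2@ < @I10@."""
    return tuple(int(part) if part.isdigit() else part for part in _NAT_SPLIT.split(s))


def normalize_surname(s: str) -> str:
    """Casefold, strip diacritics and non-letter characters."""
    s = unicodedata.normalize("NFKD", s)
    s = "".join(c for c in s if not unicodedata.combining(c))
    return "".join(c for c in s.casefold() if c.isalpha())


def jaro(s1: str, s2: str) -> float:
    if s1 == s2:
        return 1.0
    n1, n2 = len(s1), len(s2)
    if n1 == 0 or n2 == 0:
        return 0.0
    window = max(n1, n2) // 2 - 1
    if window < 0:
        window = 0
    flags1 = [False] * n1
    flags2 = [False] * n2
    m = 0
    for i, c in enumerate(s1):
        lo = max(0, i - window)
        hi = min(n2, i + window + 1)
        for j in range(lo, hi):
            if not flags2[j] and s2[j] == c:
                flags1[i] = flags2[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    # transpositions: matched characters out of order, halved
    k = 0
    t = 0
    for i in range(n1):
        if flags1[i]:
            while not flags2[k]:
                k += 1
            if s1[i] != s2[k]:
                t += 1
            k += 1
    t //= 2
    return (m / n1 + m / n2 + (m - t) / m) / 3.0


def jaro_winkler(s1: str, s2: str, prefix_scale: float = 0.1, max_prefix: int = 4) -> float:
    j = jaro(s1, s2)
    prefix = 0
    for a, b in zip(s1, s2):
        if a != b or prefix >= max_prefix:
            break
        prefix += 1
    return j + prefix * prefix_scale * (1.0 - j)
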