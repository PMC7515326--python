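"""Independent brute-force oracles used to validate the optimized code paths."""

from __future__ import annotations


def lz76_exhaustive(seq) -> int:
    """Naive exhaustive-history LZ76 word count.

    Each word is the shortest prefix of the remainder that does not occur as
    a substring of everything up to (but excluding) the word's last symbol;
    the final word counts even if it is reproducible.  Substring scanning on
    bytes; deliberately simple and independent of the package.
    """
    vals = [int(v) for v in seq]
    if not vals:
        raise ValueError("empty sequence")
    if not all(0 <= v < 256 for v in vals):
        raise ValueError("byte-based oracle supports alphabets up to 256")
    s = bytes(vals)
    n = len(s)
    i = 0
    c = 0
    while i < n:
        k = 1
        while i + k <= n and s[i:i + k] in s[:i + k - 1]:
            k += 1
        if i + k > n:
            k = n - i
        c += 1
        i += k
    return c


def connected_components(mask_indices, adjacency) -> list[frozenset]:
    """Breadth-first-search connected components of a source subset."""
    member = set(int(i) for i in mask_indices)
    seen = set()
    comps = []
    for start in sorted(member):
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        seen.add(start)
        while frontier:
            node = frontier.pop()
            for nb in adjacency[node]:
                nb = int(nb)
                if nb in member and nb not in seen:
                    seen.add(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(frozenset(comp))
    return comps
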