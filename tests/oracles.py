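"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own algorithms: seed sites are found
by per-window string comparison against Biopython-built site strings, the
alignment oracle is a memoized recursion over alignment endings, and the
structure oracle exhaustively enumerates every non-crossing structure and
scores it by definition.
"""

from __future__ import annotations

import functools
import sys

from Bio.Seq import Seq

from wingnet import targets

sys.setrecursionlimit(200_000)

_PAIRABLE = {
    ("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G"),
}


def brute_force_seed_sites(mature: str, utr: str) -> list[tuple[int, str]]:
    """All (core position, most-specific class) via explicit window checks."""
    m = mature.replace("T", "U").upper()
    u = utr.replace("T", "U").upper()
    site6 = str(Seq(m[1:7]).reverse_complement_rna())
    site7m8 = str(Seq(m[1:8]).reverse_complement_rna())
    site7a1 = site6 + "A"
    site8 = site7m8 + "A"
    rank = {"8mer": 4, "7mer-m8": 3, "7mer-A1": 2, "6mer": 1}
    best: dict = {}
    # every window contributes its class at its core position; most specific wins
    for w in range(len(u)):
        for cls, site, core in (
            ("8mer", site8, w + 1),
            ("7mer-m8", site7m8, w + 1),
            ("7mer-A1", site7a1, w),
            ("6mer", site6, w),
        ):
            if u[w : w + len(site)] == site:
                if core not in best or rank[cls] > rank[best[core]]:
                    best[core] = cls
    return sorted(best.items())


def local_affine_oracle(a: str, b: str) -> float:
    """Best local anti-parallel alignment score by memoized recursion over
    alignment endings (three gap states), independent of the Gotoh matrices."""
    b = b[::-1]
    na, nb = len(a), len(b)
    neg = float("-inf")

    def sub(i: int, j: int) -> float:
        return targets._substitution(a[i - 1], b[j - 1], i)

    @functools.lru_cache(maxsize=None)
    def ending(i: int, j: int, state: str) -> float:
        if i == 0 or j == 0:
            return neg
        if state == "M":
            prev = max(ending(i - 1, j - 1, s) for s in ("M", "X", "Y"))
            return max(prev, 0.0) + sub(i, j)
        if state == "X":
            return max(ending(i - 1, j, "M") - 9.0, ending(i - 1, j, "X") - 4.0)
        return max(ending(i, j - 1, "M") - 9.0, ending(i, j - 1, "Y") - 4.0)

    best = 0.0
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            for s in ("M", "X", "Y"):
                best = max(best, ending(i, j, s))
    ending.cache_clear()
    return best


def enumerate_structures(seq: str, forbidden: frozenset = frozenset()):
    """Every non-crossing pair set with hairpin loops >= 3 on ``seq``."""
    n = len(seq)

    @functools.lru_cache(maxsize=None)
    def structs(i: int, j: int):
        if j - i < 4:
            return (frozenset(),)
        out = list(structs(i + 1, j))
        for k in range(i + 4, j + 1):
            if (
                i in forbidden
                or k in forbidden
                or (seq[i], seq[k]) not in _PAIRABLE
            ):
                continue
            for left in structs(i + 1, k - 1):
                for right in structs(k + 1, j):
                    out.append(left | right | {(i, k)})
        return tuple(out)

    result = structs(0, n - 1) if n else (frozenset(),)
    structs.cache_clear()
    return result


def structure_energy(seq: str, structure: frozenset) -> float:
    """Energy by definition: sum stack energies over adjacent nested pairs."""
    e = 0.0
    for (i, j) in structure:
        if (i + 1, j - 1) in structure:
            e += targets._stack_energy(
                targets._pair_kind(seq[i], seq[j]),
                targets._pair_kind(seq[i + 1], seq[j - 1]),
            )
    return e


def brute_force_mfe(seq: str, forbidden: frozenset = frozenset()) -> float:
    return min(
        structure_energy(seq, s) for s in enumerate_structures(seq, forbidden)
    )
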