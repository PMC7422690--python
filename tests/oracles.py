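"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions (substring enumeration,
subset enumeration) rather than sharing code paths with the package.
"""

from itertools import combinations

IUPAC = {
    "A": set("A"), "C": set("C"), "G": set("G"), "T": set("T"),
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGT"),
}
COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def bases_pair(x: str, y: str) -> bool:
    """Two IUPAC codes can form at least one Watson-Crick pair."""
    return any(COMP[p] in IUPAC[y] for p in IUPAC[x])


def stems_pair(a: str, b: str) -> bool:
    """a (5'->3') pairs antiparallel with b (5'->3'), full length."""
    n = len(a)
    return len(b) == n and all(bases_pair(a[k], b[n - 1 - k]) for k in range(n))


def duplex_max_run(a: str, b: str) -> int:
    """Longest L such that some a[i:i+L] pairs antiparallel with some b[j:j+L]."""
    best = 0
    for L in range(1, min(len(a), len(b)) + 1):
        found = False
        for i in range(len(a) - L + 1):
            for j in range(len(b) - L + 1):
                if stems_pair(a[i : i + L], b[j : j + L]):
                    found = True
                    break
            if found:
                break
        if found:
            best = L
    return best


def duplex_three_prime_run(a: str, b: str) -> int:
    """Longest paired stretch that includes the 3' terminal base of a or b."""
    best = 0
    for L in range(1, min(len(a), len(b)) + 1):
        for i in range(len(a) - L + 1):
            for j in range(len(b) - L + 1):
                if i + L != len(a) and j + L != len(b):
                    continue
                if stems_pair(a[i : i + L], b[j : j + L]):
                    best = max(best, L)
    return best


def has_hairpin(s: str, stem_min: int, loop_min: int) -> bool:
    """Two non-overlapping complementary stretches around a loop >= loop_min."""
    n = len(s)
    for i in range(n):
        for j in range(i + stem_min + loop_min, n - stem_min + 1):
            if stems_pair(s[i : i + stem_min], s[j : j + stem_min]):
                return True
    return False


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def max_compatible_subset_size(candidates: list[str], min_distance: int) -> int:
    """Exhaustive search over all subsets (pools <= ~15)."""
    best = 0
    n = len(candidates)
    for mask in range(1 << n):
        members = [candidates[i] for i in range(n) if mask >> i & 1]
        if len(members) <= best:
            continue
        if all(hamming(x, y) >= min_distance for x, y in combinations(members, 2)):
            best = len(members)
    return best


def sliding_flank_matches(barcode: str, flank: str) -> int:
    """Max IUPAC-compatible matches of the barcode at any offset on the flank."""
    best = 0
    for off in range(len(flank) - len(barcode) + 1):
        m = sum(
            1
            for k in range(len(barcode))
            if IUPAC[barcode[k]] & IUPAC[flank[off + k]]
        )
        best = max(best, m)
    return best
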