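"""Nucleotide-string primitives shared by the whole toolkit.

Everything downstream (barcode design, tag schemes, demultiplexing) reduces to
a small algebra over IUPAC codes: expansion-set compatibility, Hamming-style
distances on degenerate strings, homopolymer runs, and match-count screens for
secondary structure (hairpins, homo-/heteroduplexes).  Oligos are plain
uppercase strings over the 15-letter IUPAC alphabet; orientation is always
written 5'->3'.

Structure screens here are combinatorial (longest compatible complementary
run), not thermodynamic: no nearest-neighbour free energies are computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

__all__ = [
    "IUPAC",
    "Oligo",
    "DuplexReport",
    "revcomp",
    "iupac_compatible",
    "iupac_distance",
    "max_homopolymer",
    "duplex_scan",
    "hairpin_scan",
    "consensus",
]

#: IUPAC degenerate nucleotide codes and their expansion sets.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_SET_TO_CODE = {v: k for k, v in IUPAC.items()}

# (x, y) -> expansion sets intersect
_COMPAT = {
    (x, y): bool(IUPAC[x] & IUPAC[y]) for x in IUPAC for y in IUPAC
}
# (x, y) -> x can base-pair with y (x intersects the complement set of y)
_PAIRS = {
    (x, y): bool(IUPAC[x] & frozenset(_COMPLEMENT[b] for b in IUPAC[y]))
    for x in IUPAC
    for y in IUPAC
}


@dataclass(frozen=True)
class Oligo:
    """A named nucleotide string over the IUPAC alphabet, stored uppercase, 5'->3'."""

    sequence: str
    name: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("oligo sequence must be non-empty")
        bad = set(seq) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in {self.name or 'oligo'}: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


OligoLike = Union[str, Oligo]


def as_seq(o: OligoLike) -> str:
    """Coerce an Oligo or plain string to a validated uppercase sequence."""
    if isinstance(o, Oligo):
        return o.sequence
    return Oligo(str(o)).sequence


def revcomp(o: OligoLike) -> OligoLike:
    """Reverse complement under IUPAC rules (R<->Y, K<->M, B<->V, D<->H; S, W, N fixed).

    Involutive.  Returns the same type as its input; an Oligo keeps its name.
    """
    seq = as_seq(o)
    rc = "".join(_COMPLEMENT[c] for c in reversed(seq))
    if isinstance(o, Oligo):
        return Oligo(rc, o.name)
    return rc


def iupac_compatible(a: str, b: str) -> bool:
    """True iff the expansion sets of two single IUPAC codes intersect."""
    try:
        return _COMPAT[(a.upper(), b.upper())]
    except KeyError:
        raise ValueError(f"non-IUPAC code in ({a!r}, {b!r})") from None


def iupac_distance(a: OligoLike, b: OligoLike) -> int:
    """Count positions whose expansion sets are disjoint (degenerate-aware Hamming).

    Requires equal lengths.  Restricted to non-degenerate strings this is the
    ordinary Hamming distance and a true metric.
    """
    sa, sb = as_seq(a), as_seq(b)
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    return sum(1 for x, y in zip(sa, sb) if not _COMPAT[(x, y)])


def max_homopolymer(o: OligoLike) -> int:
    """Length of the longest run of one identical literal character."""
    seq = as_seq(o)
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        if run > best:
            best = run
    return best


@dataclass(frozen=True)
class DuplexReport:
    """Summary of the best ungapped antiparallel pairing between two oligos.

    max_run is the longest contiguous complementary stretch over all offsets;
    three_prime_run is the longest such stretch anchored at the 3' terminus of
    either oligo (the primer-extension-relevant case); offset locates the best
    run (shift of revcomp(b) relative to a).
    """

    max_run: int
    three_prime_run: int
    offset: int

    def exceeds(self, max_run: int, three_prime_run: int) -> bool:
        """True if either severity threshold is reached (reject condition)."""
        return self.max_run >= max_run or self.three_prime_run >= three_prime_run


def duplex_scan(a: OligoLike, b: OligoLike) -> DuplexReport:
    """Slide ``a`` against ``revcomp(b)`` over all ungapped offsets.

    Degenerate codes pair if their expansion sets allow any Watson-Crick pair.
    ``a is b`` (or equal strings) scans for self-dimers.
    """
    sa = as_seq(a)
    c = revcomp(as_seq(b))  # c[j] pairs position len(b)-1-j of b
    la, lc = len(sa), len(c)
    max_run = 0
    best_offset = 0
    three_prime = 0
    for offset in range(-(lc - 1), la):
        i0 = max(0, offset)
        i1 = min(la, offset + lc)
        run = 0
        run_start = i0
        for i in range(i0, i1 + 1):
            if i < i1 and _COMPAT[(sa[i], c[i - offset])]:
                if run == 0:
                    run_start = i
                run += 1
                continue
            if run:
                end = i - 1
                # a's 3' end is a[-1]; b's 3' end maps to c[0]
                anchored = end == la - 1 or run_start - offset == 0
                if run > max_run:
                    max_run, best_offset = run, offset
                if anchored and run > three_prime:
                    three_prime = run
            run = 0
    return DuplexReport(max_run=max_run, three_prime_run=three_prime, offset=best_offset)


def hairpin_scan(o: OligoLike, stem_min: int = 4, loop_min: int = 3) -> bool:
    """True iff the oligo can fold back on itself.

    Looks for two non-overlapping stretches of length >= ``stem_min`` that are
    antiparallel-complementary and separated by at least ``loop_min`` unpaired
    bases.  Degenerate codes pair by expansion-set intersection, so this is a
    worst-case (most permissive) screen.
    """
    if stem_min < 2:
        raise ValueError("stem_min must be >= 2")
    if loop_min < 3:
        raise ValueError("loop_min must be >= 3 (shorter loops cannot form)")
    s = as_seq(o)
    n, m = len(s), stem_min
    for i in range(n - 2 * m - loop_min + 1):
        for j in range(i + m + loop_min, n - m + 1):
            if all(_PAIRS[(s[i + k], s[j + m - 1 - k])] for k in range(m)):
                return True
    return False


def consensus(
    alignment: Iterable[Union[str, "object"]],
    majority_threshold: float = 0.5,
) -> str:
    """Majority-rule IUPAC consensus of a gapped alignment.

    Per column, every base whose frequency among non-gap characters is at
    least ``1 - majority_threshold`` is retained and the smallest IUPAC code
    covering the retained bases is emitted (degenerate input characters
    contribute fractional counts split over their expansion set).  Columns
    that are >= 50% gaps are dropped.  If no base reaches the cutoff the most
    frequent base(s) are kept so the consensus never goes blank.
    """
    seqs = [str(getattr(s, "seq", s)).upper() for s in alignment]
    if len(seqs) < 2:
        raise ValueError("alignment must contain at least 2 sequences")
    if not 0.5 <= majority_threshold <= 1.0:
        raise ValueError("majority_threshold must be in [0.5, 1]")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("aligned sequences must have equal lengths")
    cutoff = 1.0 - majority_threshold
    out: list[str] = []
    for col in zip(*seqs):
        nongap = [ch for ch in col if ch not in "-."]
        if len(nongap) * 2 <= len(col):
            continue
        counts = {b: 0.0 for b in "ACGT"}
        for ch in nongap:
            try:
                expansion = IUPAC[ch]
            except KeyError:
                raise ValueError(f"non-IUPAC character {ch!r} in alignment") from None
            w = 1.0 / len(expansion)
            for b in expansion:
                counts[b] += w
        total = float(len(nongap))
        keep = frozenset(b for b in "ACGT" if counts[b] > 0 and counts[b] / total >= cutoff - 1e-12)
        if not keep:
            top = max(counts.values())
            keep = frozenset(b for b in "ACGT" if counts[b] >= top - 1e-12)
        out.append(_SET_TO_CODE[keep])
    return "".join(out)
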