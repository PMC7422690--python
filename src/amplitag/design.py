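"""Constraint-based design of sample-indexing barcodes for tagged primers.

A barcode is an 8-nt (configurable) ACGT word prepended to the 5' end of a PCR
primer.  A usable set must jointly satisfy:

* balanced composition (per-base counts and GC bounds) and no homopolymers;
* no hairpin of the tagged oligo (barcode + primer) and no self-dimer;
* no heteroduplex with the attached primer;
* no spurious annealing to the template consensus immediately flanking the
  primer site (the barcode must not extend the primer's match);
* a minimum pairwise distance (Hamming; barcodes are fixed-length) so single
  sequencing errors can never convert one barcode into another.

The screens are match-count based (see :mod:`amplitag.oligo`); thresholds are
exposed on :class:`DesignConstraints` and default to common primer-QC practice.
"""

from __future__ import annotations

import itertools
import json
import random
import re
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from .oligo import (
    Oligo,
    OligoLike,
    as_seq,
    duplex_scan,
    hairpin_scan,
    iupac_compatible,
    iupac_distance,
    max_homopolymer,
    revcomp,
)

__all__ = [
    "DesignConstraints",
    "BarcodeSet",
    "ValidationReport",
    "enumerate_candidates",
    "screen_against_primer",
    "screen_against_flank",
    "select_set",
    "design_barcodes",
    "cross_combination_screen",
    "validate_set",
    "extract_flank",
]


@dataclass(frozen=True)
class DesignConstraints:
    """Tunable constraint chain for barcode design.

    "Balanced nucleotide content" is quantified as every base appearing
    between ``base_count_min`` and ``base_count_max`` times in an 8-mer with
    GC fraction inside ``(gc_min, gc_max)``; "no homopolymers" as runs of at
    most ``max_homopolymer_run``.  Duplex thresholds are reject-at conditions:
    a candidate fails if any scan reaches ``duplex_max_run`` total or
    ``duplex_three_prime_run`` 3'-anchored complementary bases.
    """

    barcode_length: int = 8
    min_pairwise_distance: int = 3
    max_homopolymer_run: int = 2
    base_count_min: int = 1
    base_count_max: int = 3
    gc_min: float = 0.375
    gc_max: float = 0.625
    hairpin_stem_min: int = 4
    hairpin_loop_min: int = 3
    duplex_max_run: int = 6
    duplex_three_prime_run: int = 4
    flank_match_max: int = 5
    flank_window: int = 20

    def __post_init__(self) -> None:
        if not 1 <= self.min_pairwise_distance <= self.barcode_length:
            raise ValueError("need barcode_length >= min_pairwise_distance >= 1")
        for name in (
            "barcode_length", "max_homopolymer_run", "base_count_max",
            "hairpin_stem_min", "hairpin_loop_min", "duplex_max_run",
            "duplex_three_prime_run", "flank_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.base_count_min < 0 or self.flank_match_max < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class BarcodeSet:
    """A validated, ordered collection of same-length ACGT barcodes.

    Carries the primer the barcodes are attached to (5' side), the constraint
    set that produced them, a per-barcode audit trail of filter outcomes, and
    a warning when fewer than the requested number could be selected.
    """

    barcodes: list[str]
    attached_primer: str
    orientation: str  # "forward" | "reverse"
    constraints: DesignConstraints
    audit: dict[str, dict] = field(default_factory=dict)
    warning: Optional[str] = None

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")
        self.barcodes = [as_seq(b) for b in self.barcodes]

    def __len__(self) -> int:
        return len(self.barcodes)

    @property
    def tagged_oligos(self) -> list[str]:
        """Barcode + primer concatenations (barcode 5' of the primer)."""
        return [b + self.attached_primer for b in self.barcodes]

    def min_pairwise_distance(self) -> int:
        if len(self.barcodes) < 2:
            return len(self.barcodes[0]) if self.barcodes else 0
        return min(
            iupac_distance(a, b) for a, b in itertools.combinations(self.barcodes, 2)
        )

    def names(self, prefix: str = "bc") -> list[str]:
        tag = "F" if self.orientation == "forward" else "R"
        return [f"{prefix}{tag}{i + 1:02d}" for i in range(len(self.barcodes))]

    def to_tsv(self) -> str:
        lines = ["name\tsequence\torientation\tprimer"]
        for name, b in zip(self.names(), self.barcodes):
            lines.append(f"{name}\t{b}\t{self.orientation}\t{self.attached_primer}")
        return "\n".join(lines) + "\n"

    def to_fasta(self) -> str:
        return "".join(
            f">{name}\n{b}\n" for name, b in zip(self.names(), self.barcodes)
        )

    def report_json(self) -> str:
        return json.dumps(
            {
                "orientation": self.orientation,
                "primer": self.attached_primer,
                "n_barcodes": len(self.barcodes),
                "min_pairwise_distance": self.min_pairwise_distance(),
                "constraints": asdict(self.constraints),
                "warning": self.warning,
                "barcodes": dict(zip(self.names(), self.barcodes)),
                "audit": self.audit,
            },
            indent=2,
        )


def _composition_ok(seq: str, c: DesignConstraints) -> bool:
    counts = {b: seq.count(b) for b in "ACGT"}
    if any(not c.base_count_min <= n <= c.base_count_max for n in counts.values()):
        return False
    gc = (counts["G"] + counts["C"]) / len(seq)
    if not c.gc_min - 1e-12 <= gc <= c.gc_max + 1e-12:
        return False
    return max_homopolymer(seq) <= c.max_homopolymer_run


def enumerate_candidates(constraints: DesignConstraints) -> list[str]:
    """All 4^L words of the configured length passing composition and
    homopolymer filters, in lexicographic order.

    Refuses lengths above 12 (the full enumeration would exceed 16M words).
    """
    L = constraints.barcode_length
    if L > 12:
        raise ValueError("enumeration limited to barcode_length <= 12")
    return [
        "".join(word)
        for word in itertools.product("ACGT", repeat=L)
        if _composition_ok("".join(word), constraints)
    ]


def screen_against_primer(
    b: OligoLike, primer: OligoLike, constraints: DesignConstraints
) -> tuple[bool, dict]:
    """Structure screen of one barcode against its primer.

    Passes iff the tagged oligo (barcode + primer) forms no hairpin, the
    barcode forms no heteroduplex with the primer, and no self-dimer, all at
    the constraint thresholds.  Returns (passed, audit record).
    """
    bs, ps = as_seq(b), as_seq(primer)
    if set(bs) - set("ACGT"):
        raise ValueError("barcodes must be ACGT-only")
    c = constraints
    hairpin = hairpin_scan(bs + ps, c.hairpin_stem_min, c.hairpin_loop_min)
    hetero = duplex_scan(bs, ps)
    selfd = duplex_scan(bs, bs)
    audit = {
        "hairpin": hairpin,
        "heteroduplex_max_run": hetero.max_run,
        "heteroduplex_3p_run": hetero.three_prime_run,
        "selfdimer_max_run": selfd.max_run,
        "selfdimer_3p_run": selfd.three_prime_run,
    }
    ok = (
        not hairpin
        and not hetero.exceeds(c.duplex_max_run, c.duplex_three_prime_run)
        and not selfd.exceeds(c.duplex_max_run, c.duplex_three_prime_run)
    )
    return ok, audit


def screen_against_flank(
    b: OligoLike, flank_consensus: OligoLike, constraints: DesignConstraints
) -> bool:
    """Pass iff the barcode nowhere resembles the template flank.

    Slides the barcode along the flanking consensus; at every offset the
    number of IUPAC-compatible matches must stay <= ``flank_match_max``.
    """
    bs, fs = as_seq(b), as_seq(flank_consensus)
    if len(fs) < len(bs):
        raise ValueError("flank consensus shorter than barcode")
    for off in range(len(fs) - len(bs) + 1):
        matches = sum(
            1 for k in range(len(bs)) if iupac_compatible(bs[k], fs[off + k])
        )
        if matches > constraints.flank_match_max:
            return False
    return True


def _greedy_select(candidates: Sequence[str], min_distance: int, target_size: int) -> list[str]:
    chosen: list[str] = []
    for cand in candidates:
        if all(iupac_distance(cand, x) >= min_distance for x in chosen):
            chosen.append(cand)
            if len(chosen) >= target_size:
                break
    return chosen


def _exact_select(candidates: Sequence[str], min_distance: int, target_size: int) -> list[str]:
    """Exact maximum mutually-compatible subset by branch and bound (small pools)."""
    n = len(candidates)
    compat = [
        sum(
            1 << j
            for j in range(n)
            if j != i and iupac_distance(candidates[i], candidates[j]) >= min_distance
        )
        for i in range(n)
    ]
    best: list[int] = []

    def extend(chosen: list[int], allowed: int, start: int) -> None:
        nonlocal best
        if len(best) >= target_size:
            return
        if len(chosen) > len(best):
            best = list(chosen)
        remaining = allowed >> start
        if len(chosen) + remaining.bit_count() <= len(best):
            return
        for i in range(start, n):
            if allowed >> i & 1:
                chosen.append(i)
                extend(chosen, allowed & compat[i], i + 1)
                chosen.pop()

    extend([], (1 << n) - 1, 0)
    return [candidates[i] for i in best[:target_size]]


def select_set(
    candidates: Sequence[OligoLike],
    min_distance: int,
    target_size: int,
    seed: int = 0,
    *,
    primer: OligoLike = "",
    orientation: str = "forward",
    constraints: Optional[DesignConstraints] = None,
    exact_below: int = 21,
) -> BarcodeSet:
    """Pick a subset with pairwise Hamming distance >= ``min_distance``.

    Pools smaller than ``exact_below`` are solved exactly (maximum compatible
    subset); larger pools use a seed-shuffled greedy accretion, which is
    near-maximal in practice.  Falling short of ``target_size`` sets a
    warning on the returned set rather than raising.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    seqs = [as_seq(c) for c in candidates]
    if len(set(seqs)) != len(seqs):
        raise ValueError("candidate list contains duplicates")
    if len(seqs) < exact_below:
        chosen = _exact_select(seqs, min_distance, target_size)
    else:
        order = list(seqs)
        random.Random(seed).shuffle(order)
        chosen = _greedy_select(order, min_distance, target_size)
    cons = constraints or DesignConstraints(
        barcode_length=len(seqs[0]) if seqs else 8,
        min_pairwise_distance=min_distance,
    )
    warning = None
    if len(chosen) < target_size:
        warning = f"only {len(chosen)} of {target_size} requested barcodes selectable"
    return BarcodeSet(
        barcodes=chosen,
        attached_primer=as_seq(primer) if primer else "",
        orientation=orientation,
        constraints=cons,
        warning=warning,
    )


def design_barcodes(
    primer: OligoLike,
    constraints: Optional[DesignConstraints] = None,
    target_size: int = 18,
    seed: int = 0,
    flank_consensus: Optional[OligoLike] = None,
    orientation: str = "forward",
) -> BarcodeSet:
    """Full design pipeline for one primer.

    Enumerates composition/homopolymer survivors, walks them in seed-shuffled
    order applying the structure and flank screens lazily, and greedily
    accretes barcodes at the required pairwise distance until ``target_size``
    is reached (or the pool is exhausted, which sets a warning).
    """
    c = constraints or DesignConstraints()
    ps = as_seq(primer)
    flank = as_seq(flank_consensus) if flank_consensus is not None else None
    if flank is not None and len(flank) > c.flank_window:
        flank = flank[-c.flank_window:]  # window 5'-adjacent to the primer site
    pool = enumerate_candidates(c)
    rng = random.Random(seed)
    rng.shuffle(pool)
    chosen: list[str] = []
    audit: dict[str, dict] = {}
    for cand in pool:
        if any(iupac_distance(cand, x) < c.min_pairwise_distance for x in chosen):
            continue
        ok, record = screen_against_primer(cand, ps, c)
        if not ok:
            continue
        if flank is not None and not screen_against_flank(cand, flank, c):
            continue
        chosen.append(cand)
        audit[cand] = record
        if len(chosen) >= target_size:
            break
    warning = None
    if len(chosen) < target_size:
        warning = f"only {len(chosen)} of {target_size} requested barcodes selectable"
    return BarcodeSet(
        barcodes=chosen,
        attached_primer=ps,
        orientation=orientation,
        constraints=c,
        audit=audit,
        warning=warning,
    )


def cross_combination_screen(
    fw_set: BarcodeSet, rv_set: BarcodeSet
) -> list[tuple[str, str, "object"]]:
    """Cross-dimer screen over every pair of tagged oligos from both sets.

    Scans fw x fw, rv x rv and fw x rv pairs (self-pairs included) and returns
    the (name_a, name_b, DuplexReport) triples exceeding the forward set's
    duplex thresholds.  An empty list means the combined layout passes.
    """
    c = fw_set.constraints
    tagged = list(zip(fw_set.names(), fw_set.tagged_oligos)) + list(
        zip(rv_set.names(), rv_set.tagged_oligos)
    )
    failing = []
    for (na, a), (nb, b) in itertools.combinations_with_replacement(tagged, 2):
        rep = duplex_scan(a, b)
        if rep.exceeds(c.duplex_max_run, c.duplex_three_prime_run):
            failing.append((na, nb, rep))
    return failing


@dataclass
class ValidationReport:
    """Independent re-check of every BarcodeSet invariant."""

    checks: dict[str, bool]
    offenders: dict[str, str]

    @property
    def passed(self) -> bool:
        return all(self.checks.values())

    def __str__(self) -> str:
        lines = []
        for name, ok in self.checks.items():
            line = f"{name}: {'pass' if ok else 'FAIL'}"
            if not ok and name in self.offenders:
                line += f" ({self.offenders[name]})"
            lines.append(line)
        return "\n".join(lines)


def validate_set(s: BarcodeSet, flank_consensus: Optional[OligoLike] = None) -> ValidationReport:
    """Re-check a barcode set against its own constraints, independently of
    how it was built.  Report-only; never raises on failure."""
    c = s.constraints
    checks: dict[str, bool] = {}
    offenders: dict[str, str] = {}

    checks["alphabet_acgt"] = all(not set(b) - set("ACGT") for b in s.barcodes)
    lengths_ok = all(len(b) == c.barcode_length for b in s.barcodes)
    checks["length"] = lengths_ok
    if not lengths_ok:
        offenders["length"] = next(b for b in s.barcodes if len(b) != c.barcode_length)

    dupes = len(s.barcodes) != len(set(s.barcodes))
    checks["distinct"] = not dupes
    if dupes:
        seen = set()
        offenders["distinct"] = next(b for b in s.barcodes if b in seen or seen.add(b))

    worst_pair, worst_d = None, None
    for a, b in itertools.combinations(s.barcodes, 2):
        d = iupac_distance(a, b)
        if worst_d is None or d < worst_d:
            worst_pair, worst_d = (a, b), d
    checks["min_pairwise_distance"] = worst_d is None or worst_d >= c.min_pairwise_distance
    if not checks["min_pairwise_distance"]:
        offenders["min_pairwise_distance"] = f"{worst_pair[0]} vs {worst_pair[1]} (d={worst_d})"

    bad_comp = [b for b in s.barcodes if not _composition_ok(b, c)]
    checks["composition_and_homopolymer"] = not bad_comp
    if bad_comp:
        offenders["composition_and_homopolymer"] = bad_comp[0]

    if s.attached_primer:
        bad_struct = [
            b for b in s.barcodes if not screen_against_primer(b, s.attached_primer, c)[0]
        ]
        checks["structure_with_primer"] = not bad_struct
        if bad_struct:
            offenders["structure_with_primer"] = bad_struct[0]

    if flank_consensus is not None:
        bad_flank = [
            b for b in s.barcodes if not screen_against_flank(b, flank_consensus, c)
        ]
        checks["flank"] = not bad_flank
        if bad_flank:
            offenders["flank"] = bad_flank[0]

    return ValidationReport(checks=checks, offenders=offenders)


def extract_flank(
    template_consensus: OligoLike, primer: OligoLike, window: int = 20
) -> str:
    """Locate the primer's annealing site on a template consensus and return
    the ``window`` bases immediately 5' of it (where the barcode would sit)."""
    ts, ps = as_seq(template_consensus), as_seq(primer)
    if len(ts) < len(ps):
        raise ValueError("template shorter than primer")
    best_pos, best_m = 0, -1
    for off in range(len(ts) - len(ps) + 1):
        m = sum(1 for k in range(len(ps)) if iupac_compatible(ps[k], ts[off + k]))
        if m > best_m:
            best_pos, best_m = off, m
    start = max(0, best_pos - window)
    flank = ts[start:best_pos]
    if not flank:
        raise ValueError("primer site has no 5' flank on this template")
    return flank
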