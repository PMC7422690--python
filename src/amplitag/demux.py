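"""Paired-read merging, exact dual-tag detection and sample assignment.

Demultiplexing is deliberately exact: a read is assigned only when its 5' end
equals a forward barcode + primer literally (primer degeneracies match by
IUPAC compatibility, barcode positions must be identical, no ambiguity codes
tolerated in the read) and its 3' end equals the reverse complement of a
reverse barcode + primer.  Because designed barcodes differ pairwise by at
least three bases, a single sequencing error can never convert one tag into
another — an errored tag simply fails to match and the read stays unassigned.
A read whose two tags are both valid but form a combination never assigned to
a sample is binned as a mistag (tag jump).

Boundary semantics follow strict-less-than removal throughout: merged reads
of exactly 300 bp or 100 bp overlap are kept, samples of exactly 10,000 reads
are kept.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .oligo import as_seq, iupac_compatible, revcomp
from .scheme import TagScheme

__all__ = [
    "MergedRead",
    "DemuxResult",
    "merge_pair",
    "filter_merged",
    "TagMatcher",
    "match_tags",
    "demux_reads",
    "rename_read",
    "drop_low_yield",
]

DEFAULT_MIN_LENGTH = 300
DEFAULT_MIN_OVERLAP = 100
DEFAULT_MIN_YIELD = 10_000


@dataclass
class MergedRead:
    """An assembled read pair with the overlap length that produced it."""

    sequence: str
    overlap_len: int
    quality: Optional[list[int]] = None
    read_id: str = ""

    def __post_init__(self) -> None:
        if self.overlap_len < 0 or self.overlap_len > len(self.sequence):
            raise ValueError("overlap_len must be in [0, len(sequence)]")

    def __len__(self) -> int:
        return len(self.sequence)


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y and x != "N" and y != "N")


def merge_pair(
    r1: str,
    r2: str,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
    q1: Optional[Sequence[int]] = None,
    q2: Optional[Sequence[int]] = None,
    read_id: str = "",
) -> Optional[MergedRead]:
    """Assemble a read pair by its best ungapped overlap, or return None.

    r2 is reverse-complemented and slid against r1; the largest overlap with a
    mismatch fraction <= ``max_mismatch_frac`` and length >= ``min_overlap``
    wins (ties: fewer mismatches).  Disagreements inside the overlap resolve
    toward the higher-quality base, or N without qualities.  A 16-nt exact
    seed match is tried first; the exhaustive scan only runs when it fails.
    """
    s1 = as_seq(r1)
    c = revcomp(as_seq(r2))
    cq = list(reversed(q2)) if q2 is not None else None
    l1, lc = len(s1), len(c)

    def overlap_at(offset: int) -> tuple[int, int]:
        i0, i1 = max(0, offset), min(l1, offset + lc)
        ov = i1 - i0
        if ov < max(min_overlap, 1):
            return -1, 0
        mm = _mismatches(s1[i0:i1], c[i0 - offset : i1 - offset])
        if mm > max_mismatch_frac * ov:
            return -1, 0
        return ov, mm

    candidates: list[tuple[int, int, int]] = []  # (overlap, -mm, offset)
    seed = c[:16]
    if len(seed) == 16 and "N" not in seed:
        pos = s1.find(seed)
        while pos != -1:
            ov, mm = overlap_at(pos)
            if ov > 0:
                candidates.append((ov, -mm, pos))
            pos = s1.find(seed, pos + 1)
    if not candidates:
        for offset in range(-(lc - 1), l1):
            ov, mm = overlap_at(offset)
            if ov > 0:
                candidates.append((ov, -mm, offset))
    if not candidates:
        return None
    ov, neg_mm, offset = max(candidates, key=lambda t: (t[0], t[1], -abs(t[2])))

    start, end = min(0, offset), max(l1, offset + lc)
    seq_chars: list[str] = []
    quals: list[int] = []
    for pos in range(start, end):
        in1 = 0 <= pos < l1
        j = pos - offset
        in2 = 0 <= j < lc
        if in1 and in2:
            b1, b2 = s1[pos], c[j]
            if b1 == b2 or b2 == "N":
                b, q = b1, (q1[pos] if q1 is not None else 40)
            elif b1 == "N":
                b, q = b2, (cq[j] if cq is not None else 40)
            elif q1 is not None and cq is not None:
                b, q = (b1, q1[pos]) if q1[pos] >= cq[j] else (b2, cq[j])
            else:
                b, q = "N", 2
        elif in1:
            b, q = s1[pos], (q1[pos] if q1 is not None else 40)
        else:
            b, q = c[j], (cq[j] if cq is not None else 40)
        seq_chars.append(b)
        quals.append(q)
    quality = quals if (q1 is not None or q2 is not None) else None
    return MergedRead("".join(seq_chars), overlap_len=ov, quality=quality, read_id=read_id)


def filter_merged(
    reads: Iterable[MergedRead],
    min_length: int = DEFAULT_MIN_LENGTH,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> dict[str, list[MergedRead]]:
    """Partition merged reads into kept / too_short / low_overlap bins.

    Removal is strict-less-than: reads of exactly ``min_length`` bases or
    ``min_overlap`` overlap are kept.
    """
    out: dict[str, list[MergedRead]] = {"kept": [], "too_short": [], "low_overlap": []}
    for r in reads:
        if len(r) < min_length:
            out["too_short"].append(r)
        elif r.overlap_len < min_overlap:
            out["low_overlap"].append(r)
        else:
            out["kept"].append(r)
    return out


class TagMatcher:
    """Precomputed exact matcher for one tag scheme.

    Barcode positions must match literally; degenerate primer positions match
    any read base inside the code's expansion set; N in the read never
    matches.  Reads failing forward orientation are retried reverse-
    complemented.
    """

    def __init__(self, scheme: TagScheme):
        if not scheme.fw_primer or not scheme.rv_primer:
            raise ValueError("scheme must carry fw_primer and rv_primer for matching")
        self.scheme = scheme
        self.fw_primer = as_seq(scheme.fw_primer)
        self.rv_primer = as_seq(scheme.rv_primer)
        self.fw_len = len(scheme.grid.fw_tags[0].sequence)
        self.rv_len = len(scheme.grid.rv_tags[0].sequence)
        self.fw_index = {t.sequence: i for i, t in enumerate(scheme.grid.fw_tags)}
        # 3' end of the merged read shows revcomp(rv_tag)
        self.rv_index = {
            str(revcomp(t.sequence)): i for i, t in enumerate(scheme.grid.rv_tags)
        }
        self.rv_primer_rc = str(revcomp(self.rv_primer))
        self.cell_to_sample = {cell: sid for sid, cell in scheme.assignments.items()}

    def _primer_matches(self, read_part: str, primer_part: str) -> bool:
        if len(read_part) != len(primer_part):
            return False
        return all(
            r in "ACGT" and iupac_compatible(r, p)
            for r, p in zip(read_part, primer_part)
        )

    def _match_one_orientation(self, seq: str):
        fL, pF = self.fw_len, self.fw_primer
        rL, pR_rc = self.rv_len, self.rv_primer_rc
        head_len = fL + len(pF)
        tail_len = rL + len(pR_rc)
        if len(seq) < head_len + tail_len:
            return None
        fi = self.fw_index.get(seq[:fL])
        if fi is None or not self._primer_matches(seq[fL:head_len], pF):
            return None
        ri = self.rv_index.get(seq[-rL:])
        if ri is None or not self._primer_matches(
            seq[-tail_len:-rL], pR_rc
        ):
            return None
        return fi, ri, seq[head_len : len(seq) - tail_len]

    def match(self, read: Union[str, MergedRead]) -> tuple[str, Optional[str], Optional[str]]:
        """Classify one read: returns (status, sample_id, trimmed_insert)
        where status is 'assigned', 'mistag' or 'unassigned'."""
        seq = read.sequence if isinstance(read, MergedRead) else as_seq(read)
        hit = self._match_one_orientation(seq)
        if hit is None:
            hit = self._match_one_orientation(str(revcomp(seq)))
        if hit is None:
            return "unassigned", None, None
        fi, ri, insert = hit
        sample = self.cell_to_sample.get((fi, ri))
        if sample is None:
            return "mistag", None, insert
        return "assigned", sample, insert


def match_tags(
    read: Union[str, MergedRead], scheme: TagScheme
) -> tuple[str, Optional[str], Optional[str]]:
    """One-shot exact tag match against a scheme (see :class:`TagMatcher`)."""
    return TagMatcher(scheme).match(read)


@dataclass
class DemuxResult:
    """Outcome of demultiplexing one run: every input read lands in exactly
    one bin, so bin counts always sum to the input total."""

    assigned: dict[str, list[tuple[str, str]]]  # sample -> [(read_id, insert)]
    bins: dict[str, int]
    mistag_reads: list[str] = field(default_factory=list)
    unassigned_reads: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.bins.values())

    def sample_counts(self) -> dict[str, int]:
        return {s: len(reads) for s, reads in self.assigned.items()}

    def counts_table(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "bin": "assigned", "reads": len(v)}
            for s, v in self.assigned.items()
        ]
        for b in ("mistag", "unassigned", "too_short", "low_overlap"):
            rows.append({"sample_id": "", "bin": b, "reads": self.bins.get(b, 0)})
        return pd.DataFrame(rows)


def demux_reads(
    merged: Iterable[MergedRead],
    scheme: TagScheme,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DemuxResult:
    """Length/overlap filter then exact tag classification of merged reads."""
    parts = filter_merged(merged, min_length=min_length, min_overlap=min_overlap)
    matcher = TagMatcher(scheme)
    assigned: dict[str, list[tuple[str, str]]] = {s: [] for s in scheme.samples}
    bins = {
        "assigned": 0,
        "mistag": 0,
        "unassigned": 0,
        "too_short": len(parts["too_short"]),
        "low_overlap": len(parts["low_overlap"]),
    }
    mistags: list[str] = []
    unassigned: list[str] = []
    for r in parts["kept"]:
        status, sample, insert = matcher.match(r)
        bins[status] += 1
        if status == "assigned":
            assigned[sample].append((r.read_id, insert))
        elif status == "mistag":
            mistags.append(r.read_id)
        else:
            unassigned.append(r.read_id)
    return DemuxResult(
        assigned=assigned, bins=bins, mistag_reads=mistags, unassigned_reads=unassigned
    )


def rename_read(sample_id: str, year: int, ecosystem: str, serial: int) -> str:
    """Canonical read identifier: ``{sample}_{year}_{G|F}_{serial}``."""
    if ecosystem not in ("G", "F"):
        raise ValueError("ecosystem must be 'G' (grassland) or 'F' (forest)")
    return f"{sample_id}_{year}_{ecosystem}_{serial}"


def drop_low_yield(
    counts: Mapping[str, int], min_reads: int = DEFAULT_MIN_YIELD
) -> dict[str, int]:
    """Remove samples with fewer than ``min_reads`` reads (boundary kept)."""
    return {s: n for s, n in counts.items() if n >= min_reads}
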