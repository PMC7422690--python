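"""Dual-index tag schemes over the forward x reverse barcode grid.

With F forward and R reverse barcoded primers, F*R combinations are available
to label samples.  Deliberately leaving a fraction of combinations unused
makes tag jumping (mistagging) observable: a read whose two tags are both
valid but whose pair was never assigned to a sample must carry at least one
jumped tag.  The scheme builder balances tag usage across rows and columns so
the unused cells are spread through the grid and the exposure to mistag
detection is near-maximal.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence, Union

from .design import BarcodeSet
from .oligo import as_seq

__all__ = ["Tag", "Grid", "TagScheme", "build_grid", "select_combinations", "mistag_exposure"]


class Tag(NamedTuple):
    name: str
    sequence: str


def _as_tags(x: Union[BarcodeSet, Sequence], prefix: str) -> list[Tag]:
    if isinstance(x, BarcodeSet):
        return [Tag(n, s) for n, s in zip(x.names(), x.barcodes)]
    tags = []
    for i, item in enumerate(x):
        if isinstance(item, Tag):
            tags.append(item)
        elif isinstance(item, (tuple, list)) and len(item) == 2:
            tags.append(Tag(str(item[0]), as_seq(item[1])))
        else:
            tags.append(Tag(f"{prefix}{i + 1:02d}", as_seq(item)))
    return tags


@dataclass(frozen=True)
class Grid:
    """The F x R combination grid: rows are forward tags, columns reverse tags."""

    fw_tags: tuple[Tag, ...]
    rv_tags: tuple[Tag, ...]

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.fw_tags), len(self.rv_tags)

    @property
    def n_cells(self) -> int:
        f, r = self.shape
        return f * r


def build_grid(
    fw: Union[BarcodeSet, Sequence], rv: Union[BarcodeSet, Sequence]
) -> Grid:
    """Build the combination grid from two barcode sets (or tag lists)."""
    fw_tags = _as_tags(fw, "bcF")
    rv_tags = _as_tags(rv, "bcR")
    if not fw_tags or not rv_tags:
        raise ValueError("both tag sets must be non-empty")
    return Grid(tuple(fw_tags), tuple(rv_tags))


@dataclass
class TagScheme:
    """Mapping sample -> (forward tag, reverse tag) plus the unused cells."""

    grid: Grid
    assignments: dict[str, tuple[int, int]]
    fw_primer: str = ""
    rv_primer: str = ""

    def __post_init__(self) -> None:
        cells = list(self.assignments.values())
        if len(set(cells)) != len(cells):
            raise ValueError("assignments must be injective on grid cells")
        f, r = self.grid.shape
        for fi, ri in cells:
            if not (0 <= fi < f and 0 <= ri < r):
                raise ValueError(f"cell ({fi},{ri}) outside the {f}x{r} grid")

    @property
    def unused(self) -> set[tuple[int, int]]:
        f, r = self.grid.shape
        used = set(self.assignments.values())
        return {(i, j) for i in range(f) for j in range(r)} - used

    @property
    def samples(self) -> list[str]:
        return list(self.assignments)

    def tags_for(self, sample_id: str) -> tuple[Tag, Tag]:
        fi, ri = self.assignments[sample_id]
        return self.grid.fw_tags[fi], self.grid.rv_tags[ri]

    # --- serialization ------------------------------------------------------

    def to_tsv(self) -> str:
        """TSV with a commented header carrying the full tag lists (so unused
        rows/columns survive a round trip)."""
        lines = [
            "#fw_primer\t" + self.fw_primer,
            "#rv_primer\t" + self.rv_primer,
            "#fw_tags\t" + ";".join(f"{t.name}={t.sequence}" for t in self.grid.fw_tags),
            "#rv_tags\t" + ";".join(f"{t.name}={t.sequence}" for t in self.grid.rv_tags),
            "sample_id\tfw_name\tfw_seq\trv_name\trv_seq",
        ]
        for sid, (fi, ri) in self.assignments.items():
            ft, rt = self.grid.fw_tags[fi], self.grid.rv_tags[ri]
            lines.append(f"{sid}\t{ft.name}\t{ft.sequence}\t{rt.name}\t{rt.sequence}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "TagScheme":
        meta: dict[str, str] = {}
        rows: list[list[str]] = []
        for line in text.splitlines():
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                meta[key] = value
                continue
            rows.append(line.split("\t"))
        header, body = rows[0], rows[1:]
        if header[:5] != ["sample_id", "fw_name", "fw_seq", "rv_name", "rv_seq"]:
            raise ValueError("not a tag-scheme TSV")

        def parse_tags(spec: str) -> list[Tag]:
            return [
                Tag(*item.split("=", 1)) for item in spec.split(";") if item
            ]

        fw_tags = parse_tags(meta.get("fw_tags", ""))
        rv_tags = parse_tags(meta.get("rv_tags", ""))
        if not fw_tags:  # fall back to order of first appearance
            seen: dict[str, str] = {}
            for r in body:
                seen.setdefault(r[1], r[2])
            fw_tags = [Tag(n, s) for n, s in seen.items()]
        if not rv_tags:
            seen = {}
            for r in body:
                seen.setdefault(r[3], r[4])
            rv_tags = [Tag(n, s) for n, s in seen.items()]
        grid = Grid(tuple(fw_tags), tuple(rv_tags))
        fw_idx = {t.name: i for i, t in enumerate(grid.fw_tags)}
        rv_idx = {t.name: i for i, t in enumerate(grid.rv_tags)}
        assignments = {r[0]: (fw_idx[r[1]], rv_idx[r[3]]) for r in body}
        return cls(
            grid=grid,
            assignments=assignments,
            fw_primer=meta.get("fw_primer", ""),
            rv_primer=meta.get("rv_primer", ""),
        )


def select_combinations(
    grid: Grid, sample_ids: Sequence[str], seed: int = 0,
    fw_primer: str = "", rv_primer: str = "",
) -> TagScheme:
    """Assign samples to grid cells with balanced tag usage.

    Uses the diagonal-band construction r = k mod F, c = (k + k//lcm(F,R))
    mod R, which is injective for n <= F*R and keeps every row and column
    usage within one of the balanced value; the seed relabels rows and
    columns by random permutations, preserving both properties.
    """
    f, r = grid.shape
    n = len(sample_ids)
    if len(set(sample_ids)) != n:
        raise ValueError("sample ids must be unique")
    if n > grid.n_cells:
        raise ValueError(f"{n} samples exceed the {f}x{r} grid capacity")
    if n > 0.75 * grid.n_cells:
        import warnings

        warnings.warn(
            f"{n} samples on a {f}x{r} grid leave little head-room for mistag detection",
            stacklevel=2,
        )
    rng = random.Random(seed)
    row_perm = list(range(f))
    col_perm = list(range(r))
    rng.shuffle(row_perm)
    rng.shuffle(col_perm)
    period = math.lcm(f, r)
    assignments = {
        sid: (row_perm[k % f], col_perm[(k + k // period) % r])
        for k, sid in enumerate(sample_ids)
    }
    return TagScheme(
        grid=grid, assignments=assignments, fw_primer=fw_primer, rv_primer=rv_primer
    )


def mistag_exposure(s: TagScheme) -> float:
    """Fraction of grid cells that are unused but whose row AND column both
    label some sample — the cells where a single tag jump becomes observable."""
    used = set(s.assignments.values())
    used_rows = {fi for fi, _ in used}
    used_cols = {ri for _, ri in used}
    exposed = sum(
        1 for (fi, ri) in s.unused if fi in used_rows and ri in used_cols
    )
    return exposed / s.grid.n_cells
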