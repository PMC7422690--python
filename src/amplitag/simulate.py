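"""Synthetic inputs with ground truth for every stage of the toolkit.

Three generators emulate the study design — dual-tagged amplicons from soil
samples on an F x R index grid, a reference alignment around the primer site,
and an OTU x sample table with planted ecosystem-sharing structure and
functional-guild labels — so the whole pipeline can be exercised and checked
against known truth without any sequencing data.

What is emulated: tag layout and tag jumps (independent single-tag swaps,
uniform over used tags), skewed log-normal OTU abundances, random amplicon
orientation, truncated (short) reads, low-yield samples.  What is not:
per-base sequencing error profiles, chimeras, PCR stochasticity.  Same seed,
same outputs, byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .community import OtuTable, TraitTable
from .oligo import IUPAC, Oligo, as_seq, revcomp
from .scheme import TagScheme

__all__ = [
    "SimulationManifest",
    "SimulatedRun",
    "make_reference_alignment",
    "simulate_run",
    "make_otu_table",
    "draw_sample_yields",
]

#: trophic-guild mixture of the study community (fractions of OTUs):
#: dominated by bacterivores, sizeable omnivores/eukaryvores, few parasites.
DEFAULT_GUILD_MIXTURE = {
    "bacterivore": 0.50,
    "omnivore": 0.23,
    "eukaryvore": 0.10,
    "plant parasite": 0.05,
    "hyperparasite of Oomycota": 0.008,
    "unknown": 0.112,
}

_GUILD_DEFAULTS = {
    # nutrition -> (order, morphology, locomotion)
    "bacterivore": ("Glissomonadida", "naked flagellate", "creeping/gliding"),
    "omnivore": ("Cercomonadida", "amoeboflagellate", "creeping/gliding"),
    "eukaryvore": ("Vampyrellida", "naked amoeba", "creeping/gliding"),
    "plant parasite": ("Plasmodiophorida", "naked amoeba", "non-motile"),
    "hyperparasite of Oomycota": ("Plasmodiophorida", "naked amoeba", "non-motile"),
    "autotroph": ("Chlorarachnida", "naked flagellate", "swimming"),
    "unknown": ("Cryomonadida", "testate-organic/agglutinated", "creeping/gliding"),
}

_ENDOMYXA_GUILDS = {"plant parasite", "hyperparasite of Oomycota"}


# --- reference alignment --------------------------------------------------------


def make_reference_alignment(
    n_seqs: int = 50,
    length: int = 120,
    primer: Union[str, Oligo] = "GTTAAAARGCTCGTAGTYG",
    primer_pos: int = 40,
    rev_primer: Optional[Union[str, Oligo]] = None,
    rev_primer_pos: Optional[int] = None,
    flank_conservation: float = 0.9,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Ungapped reference alignment whose consensus carries the given primer.

    At primer columns the bases of each degenerate code are cycled across
    sequences, so a majority-rule consensus reproduces the code exactly.
    Elsewhere each sequence shows the template base with probability
    ``flank_conservation``, otherwise a uniform draw of the other three.
    Returns (name, sequence) tuples.
    """
    ps = as_seq(primer)
    if primer_pos < 0 or primer_pos + len(ps) > length:
        raise ValueError("primer site outside sequence")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    template = rng.choice(bases, size=length)
    planted: dict[int, str] = {primer_pos + k: ps[k] for k in range(len(ps))}
    if rev_primer is not None:
        if rev_primer_pos is None:
            raise ValueError("rev_primer_pos required with rev_primer")
        rp = str(revcomp(as_seq(rev_primer)))  # template-sense
        if rev_primer_pos < 0 or rev_primer_pos + len(rp) > length:
            raise ValueError("reverse primer site outside sequence")
        for k, code in enumerate(rp):
            planted[rev_primer_pos + k] = code
    records = []
    for s in range(n_seqs):
        chars = []
        for pos in range(length):
            code = planted.get(pos)
            if code is not None:
                expansion = sorted(IUPAC[code])
                chars.append(expansion[s % len(expansion)])
            elif rng.random() < flank_conservation:
                chars.append(template[pos])
            else:
                others = [b for b in "ACGT" if b != template[pos]]
                chars.append(others[rng.integers(0, 3)])
        records.append((f"ref{s + 1:03d}", "".join(chars)))
    return records


# --- amplicon run ---------------------------------------------------------------


@dataclass
class SimulationManifest:
    """Ground truth of one simulated run; fully determines regeneration."""

    seed: int
    rho_mistag: float
    short_frac: float
    flip_frac: float
    read_length: int
    compositions: dict[str, list[float]]
    reads: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def true_sample_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.reads:
            counts[r["sample"]] = counts.get(r["sample"], 0) + 1
        return counts


@dataclass
class SimulatedRun:
    """Paired reads plus their manifest."""

    pairs: list[tuple[str, str, str]]  # (read_id, r1, r2)
    manifest: SimulationManifest
    scheme: TagScheme

    def write_fastq(self, r1_path, r2_path) -> None:
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            for rid, r1, r2 in self.pairs:
                f1.write(f"@{rid}/1\n{r1}\n+\n{'I' * len(r1)}\n")
                f2.write(f"@{rid}/2\n{r2}\n+\n{'I' * len(r2)}\n")


def _concretize(primer: str, rng: np.random.Generator) -> str:
    return "".join(
        c if c in "ACGT" else sorted(IUPAC[c])[rng.integers(0, len(IUPAC[c]))]
        for c in primer
    )


def simulate_run(
    scheme: TagScheme,
    compositions: Optional[dict[str, Sequence[float]]] = None,
    rho_mistag: float = 0.01,
    short_frac: float = 0.0,
    reads_per_sample: Union[int, dict[str, int]] = 1000,
    n_otus: int = 30,
    read_length: int = 250,
    flip_frac: float = 0.5,
    lognormal_sigma: float = 1.5,
    seed: int = 0,
) -> SimulatedRun:
    """Simulate one dual-tagged amplicon run over a tag scheme.

    Each read carries its sample's correct tag pair except a ``rho_mistag``
    fraction, which has one tag (side chosen 50/50) swapped uniformly to a
    different *used* tag of that side — landing in a used cell (silently wrong
    sample) or an unused cell (observable mistag) according to the grid.  A
    ``short_frac`` fraction is truncated below 300 bp.  Amplicon orientation
    is random (``flip_frac``).  Insert lengths of 260-340 nt keep clean merged
    reads above the 300 bp / 100 bp-overlap gates at 2 x 250 nt reads.
    """
    for name, rate in (("rho_mistag", rho_mistag), ("short_frac", short_frac), ("flip_frac", flip_frac)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    samples = scheme.samples
    fw_primer = as_seq(scheme.fw_primer)
    rv_primer = as_seq(scheme.rv_primer)

    # OTU reference inserts
    bases = np.array(list("ACGT"))
    insert_lens = rng.integers(260, 341, size=n_otus)
    inserts = ["".join(rng.choice(bases, size=n)) for n in insert_lens]

    if compositions is None:
        compositions = {}
        for sid in samples:
            w = np.exp(rng.normal(0.0, lognormal_sigma, size=n_otus))
            compositions[sid] = (w / w.sum()).tolist()
    else:
        compositions = {
            sid: (np.asarray(p, dtype=float) / np.asarray(p, dtype=float).sum()).tolist()
            for sid, p in compositions.items()
        }

    used_fw = sorted({fi for fi, _ in scheme.assignments.values()})
    used_rv = sorted({ri for _, ri in scheme.assignments.values()})
    cell_to_sample = {cell: sid for sid, cell in scheme.assignments.items()}

    manifest = SimulationManifest(
        seed=seed,
        rho_mistag=rho_mistag,
        short_frac=short_frac,
        flip_frac=flip_frac,
        read_length=read_length,
        compositions={s: list(map(float, p)) for s, p in compositions.items()},
    )
    pairs: list[tuple[str, str, str]] = []
    for sid in samples:
        fi, ri = scheme.assignments[sid]
        probs = np.asarray(compositions[sid])
        n_reads = reads_per_sample[sid] if isinstance(reads_per_sample, dict) else reads_per_sample
        otu_draws = rng.choice(len(inserts), size=n_reads, p=probs)
        for serial, otu in enumerate(otu_draws, start=1):
            cfi, cri = fi, ri
            mistag = bool(rng.random() < rho_mistag)
            side = ""
            if mistag:
                if rng.random() < 0.5 and len(used_fw) > 1:
                    side = "fw"
                    choices = [t for t in used_fw if t != fi]
                    cfi = choices[rng.integers(0, len(choices))]
                elif len(used_rv) > 1:
                    side = "rv"
                    choices = [t for t in used_rv if t != ri]
                    cri = choices[rng.integers(0, len(choices))]
                else:
                    mistag = False
            fw_tag = scheme.grid.fw_tags[cfi].sequence
            rv_tag = scheme.grid.rv_tags[cri].sequence
            amplicon = (
                fw_tag
                + _concretize(fw_primer, rng)
                + inserts[otu]
                + str(revcomp(rv_tag + _concretize(rv_primer, rng)))
            )
            truncated = bool(rng.random() < short_frac)
            if truncated:
                amplicon = amplicon[: int(rng.integers(150, 300))]
            if rng.random() < flip_frac:
                amplicon = str(revcomp(amplicon))
            rid = f"{sid}_{serial}"
            r1 = amplicon[:read_length]
            r2 = str(revcomp(amplicon))[:read_length]
            pairs.append((rid, r1, r2))
            landing = cell_to_sample.get((cfi, cri))
            manifest.reads.append(
                {
                    "read_id": rid,
                    "sample": sid,
                    "otu": int(otu),
                    "mistag": mistag,
                    "swapped_side": side,
                    "cell": [int(cfi), int(cri)],
                    "cell_status": (
                        "own"
                        if (cfi, cri) == (fi, ri)
                        else ("other_sample" if landing is not None else "unused")
                    ),
                    "truncated": truncated,
                }
            )
    return SimulatedRun(pairs=pairs, manifest=manifest, scheme=scheme)


# --- OTU table ------------------------------------------------------------------


def _largest_remainder(fractions: dict[str, float], n: int) -> dict[str, int]:
    raw = {k: f * n for k, f in fractions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def make_otu_table(
    n_otus: int = 200,
    n_samples: int = 12,
    shared_frac: float = 0.8,
    guild_mixture: Optional[dict[str, float]] = None,
    nontarget_frac: float = 0.0,
    endomyxa_frac: float = 0.25,
    mean_depth: int = 20_000,
    lognormal_sigma: float = 1.5,
    seed: int = 0,
) -> tuple[OtuTable, TraitTable, dict]:
    """OTU x sample table with planted sharing structure and guild labels.

    ``shared_frac`` of target OTUs occur in both ecosystems (grassland G and
    forest F, half the samples each); the rest split evenly between G-only and
    F-only.  Guild labels follow ``guild_mixture`` exactly (largest-remainder
    rounding).  ``nontarget_frac`` of OTUs get a non-target phylum so the
    taxonomy filter can be exercised.  Returns (table, matching trait table,
    ground-truth dict).  Desk scale by default; pass n_otus=2101,
    n_samples=600 for the study-scale layout.
    """
    if not 0.0 <= shared_frac <= 1.0 or not 0.0 <= nontarget_frac <= 1.0:
        raise ValueError("fractions must be in [0, 1]")
    if n_samples < 2:
        raise ValueError("need at least one sample per ecosystem")
    mixture = dict(guild_mixture or DEFAULT_GUILD_MIXTURE)
    if abs(sum(mixture.values()) - 1.0) > 1e-9:
        raise ValueError("guild mixture must sum to 1")
    rng = np.random.default_rng(seed)

    n_g = n_samples // 2 + n_samples % 2
    regions = ["Alb", "Hainich", "Schorfheide"]
    prefix_g = {"Alb": "AEG", "Hainich": "HEG", "Schorfheide": "SEG"}
    prefix_f = {"Alb": "AEW", "Hainich": "HEW", "Schorfheide": "SEW"}
    sample_rows = []
    for i in range(n_samples):
        eco = "G" if i < n_g else "F"
        region = regions[i % 3]
        prefix = (prefix_g if eco == "G" else prefix_f)[region]
        sample_rows.append(
            {
                "sample_id": f"{prefix}{i + 1:03d}",
                "ecosystem": eco,
                "region": region,
                "year": 2011 if i % 2 == 0 else 2017,
            }
        )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    g_samples = samples.index[samples["ecosystem"] == "G"]
    f_samples = samples.index[samples["ecosystem"] == "F"]

    n_nontarget = int(round(nontarget_frac * n_otus))
    n_target = n_otus - n_nontarget
    n_shared = int(round(shared_frac * n_target))
    n_unique = n_target - n_shared
    n_g_only = n_unique // 2 + n_unique % 2
    n_f_only = n_unique - n_g_only

    otu_ids = [f"Otu{i + 1:04d}" for i in range(n_otus)]
    occupancy = (
        ["both"] * n_shared + ["G"] * n_g_only + ["F"] * n_f_only + ["both"] * n_nontarget
    )
    guild_counts = _largest_remainder(mixture, n_target)
    guilds: list[str] = []
    for g, c in guild_counts.items():
        guilds.extend([g] * c)
    rng.shuffle(guilds)
    guilds = guilds + [""] * n_nontarget  # non-targets carry no guild

    tax_rows = []
    trait_rows = []
    n_endo = int(round(endomyxa_frac * n_target))
    endo_flags = [True] * n_endo + [False] * (n_target - n_endo)
    rng.shuffle(endo_flags)
    for i, otu in enumerate(otu_ids):
        if i >= n_target:
            tax_rows.append(
                {"otu_id": otu, "phylum": "Fungi", "class": "", "order": "",
                 "family": "", "genus": f"Nontarget{i:04d}", "species": ""}
            )
            continue
        guild = guilds[i]
        order, morph, loco = _GUILD_DEFAULTS[guild]
        phylum = "Endomyxa" if (guild in _ENDOMYXA_GUILDS or endo_flags[i]) else "Cercozoa"
        genus = f"Genus{i + 1:04d}"
        tax_rows.append(
            {"otu_id": otu, "phylum": phylum,
             "class": "Phytomyxea" if guild in _ENDOMYXA_GUILDS else "Sarcomonadea",
             "order": order, "family": "", "genus": genus,
             "species": f"{genus} sp."}
        )
        trait_rows.append(
            {"taxon": genus, "rank": "genus", "nutrition": guild or "unknown",
             "morphology": morph, "locomotion": loco}
        )
    taxonomy = pd.DataFrame(tax_rows).set_index("otu_id")
    trait_table = TraitTable(pd.DataFrame(trait_rows))

    base_w = np.exp(rng.normal(0.0, lognormal_sigma, size=n_otus))
    counts = np.zeros((n_otus, n_samples), dtype=int)
    for j, sid in enumerate(samples.index):
        eco = samples.loc[sid, "ecosystem"]
        present = np.array(
            [occ == "both" or occ == eco for occ in occupancy]
        )
        w = base_w * present * np.exp(rng.normal(0.0, 0.5, size=n_otus))
        if w.sum() == 0:
            continue
        depth = max(1000, int(rng.normal(mean_depth, mean_depth * 0.2)))
        counts[:, j] = rng.multinomial(depth, w / w.sum())
    # force planted presence: every OTU gets >= 1 read in each ecosystem it occupies
    for i, occ in enumerate(occupancy):
        for eco, sids in (("G", g_samples), ("F", f_samples)):
            if occ in ("both", eco) and len(sids):
                cols = [samples.index.get_loc(s) for s in sids]
                if counts[i, cols].sum() == 0:
                    counts[i, cols[int(rng.integers(0, len(cols)))]] = 1

    table = OtuTable(
        pd.DataFrame(counts, index=otu_ids, columns=samples.index),
        taxonomy,
        samples,
    )
    truth = {
        "n_target": n_target,
        "n_nontarget": n_nontarget,
        "n_shared": n_shared,
        "n_g_only": n_g_only,
        "n_f_only": n_f_only,
        "guild_counts": guild_counts,
        "guild_mixture": mixture,
        "otu_guilds": dict(zip(otu_ids[:n_target], guilds[:n_target])),
        "occupancy": dict(zip(otu_ids, occupancy)),
    }
    return table, trait_table, truth


def draw_sample_yields(
    n_samples: int = 600,
    n_low_yield: int = 9,
    mean: float = 29_817.0,
    sd: float = 9_784.0,
    min_good: int = 10_300,
    max_good: int = 64_130,
    seed: int = 0,
) -> dict[str, int]:
    """Per-sample read yields matching the study's run statistics, with
    ``n_low_yield`` samples forced under the 10,000-read cutoff."""
    rng = np.random.default_rng(seed)
    yields = np.clip(
        rng.normal(mean, sd, size=n_samples).round().astype(int), min_good, max_good
    )
    low = rng.choice(n_samples, size=n_low_yield, replace=False)
    yields[low] = rng.integers(500, 10_000, size=n_low_yield)
    return {f"S{i + 1:03d}": int(y) for i, y in enumerate(yields)}
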