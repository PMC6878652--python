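"""Probe design scaffold for a custom 15K-style aCGH array.

The design targets a panel of Hirschsprung-disease candidate loci at high
probe density (300 nt to 50 kb average spacing, with optional padding around
each locus) plus a low-density genome-wide backbone used for normalisation
and for catching large events outside the candidate regions.

Coordinates are 1-based, fully closed throughout the package; conversion to
BED (0-based half-open) happens only in :mod:`cghcall.io`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PROBE_LEN = 60  # synthetic oligo length in nt

#: Default candidate-region panel: (region, chrom, locus_start, locus_end,
#: average spacing in nt, boundary padding in bp, probe count).  The probe
#: counts and spacings mirror a 15K custom design centred on HSCR candidate
#: loci; locus anchors are GRCh37-style coordinates.
DEFAULT_REGIONS: tuple[tuple[str, str, int, int, int, int, int], ...] = (
    ("RET", "10", 43572517, 43625799, 300, 100_000, 813),
    ("9q31", "9", 108_700_000, 113_260_000, 2_500, 0, 1824),
    ("9p24.1", "9", 5_400_000, 5_897_000, 3_500, 0, 142),
    ("PHOX2B", "4", 41_746_099, 41_750_987, 500, 10_000, 49),
    ("NRG1", "8", 32_400_000, 32_616_500, 500, 10_000, 473),
    ("SEMA3A/3D", "7", 83_580_000, 84_840_000, 2_500, 10_000, 508),
    ("6q25.1", "6", 149_000_000, 151_499_000, 3_500, 0, 714),
    ("21q22", "21", 27_000_000, 37_100_000, 50_000, 0, 202),
    ("3p21", "3", 44_000_000, 47_993_500, 3_500, 0, 1141),
    ("19q12", "19", 29_000_000, 32_797_500, 3_500, 0, 1085),
    ("NRTN", "19", 5_823_000, 5_837_400, 800, 5_000, 18),
    ("16q23.3", "16", 80_600_000, 83_099_000, 3_500, 0, 714),
    ("NKX2-1", "14", 36_985_000, 36_998_600, 800, 5_000, 17),
    ("SOX10", "22", 38_368_000, 38_389_600, 800, 5_000, 27),
    ("22q11.2", "22", 18_000_000, 26_100_000, 50_000, 0, 162),
    ("ECE1", "1", 21_543_000, 21_625_400, 800, 5_000, 103),
    ("ZEB2", "2", 145_141_000, 145_273_000, 800, 0, 165),
    ("EDNRB", "13", 78_469_000, 78_558_600, 800, 5_000, 112),
    ("GDNF", "5", 37_812_000, 37_845_600, 800, 5_000, 42),
    ("EDN3", "20", 57_875_000, 57_910_200, 800, 5_000, 44),
)

DEFAULT_BACKBONE_PROBES = 3130

#: Approximate GRCh37 autosome lengths used to spread backbone probes.
CHROM_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566,
}


def chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    """Natural chromosome ordering: 1..22 then X, Y, then lexicographic."""
    c = str(chrom).removeprefix("chr")
    if re.fullmatch(r"\d+", c):
        return (0, int(c))
    if c in ("X", "Y"):
        return (1, {"X": 0, "Y": 1}[c])
    return (2, c)


@dataclass(frozen=True)
class RegionSpec:
    """One row of the design table.

    ``n_probes`` may be ``None``, in which case the count is derived from the
    padded locus length divided by the average spacing.
    """

    name: str
    chrom: str
    start: int
    end: int
    spacing: int
    padding: int = 0
    n_probes: int | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"region {self.name}: end < start")
        if self.spacing <= 0:
            raise ValueError(f"region {self.name}: spacing must be positive")
        length = self.end - self.start + 1 + 2 * self.padding
        if self.n_probes is not None and self.n_probes > 0 and length <= 1:
            raise ValueError(
                f"region {self.name}: zero-length region with nonzero probe count"
            )

    @property
    def probe_count(self) -> int:
        if self.n_probes is not None:
            return self.n_probes
        length = self.end - self.start + 1 + 2 * self.padding
        return max(int(round(length / self.spacing)), 0)


class ProbeDesign:
    """An ordered probe scaffold backed by a :class:`pandas.DataFrame`.

    The frame has columns ``chrom, start, end, probe_id, region, gc`` and is
    sorted by (chromosome, start).  Most pipeline functions address probes by
    their integer row position in this frame.
    """

    COLUMNS = ("chrom", "start", "end", "probe_id", "region", "gc")

    def __init__(self, df: pd.DataFrame, regions: Sequence[RegionSpec] = ()) -> None:
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"design frame missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        order = sorted(
            range(len(df)),
            key=lambda i: (chrom_sort_key(df["chrom"].iat[i]), df["start"].iat[i]),
        )
        df = df.iloc[order].reset_index(drop=True)
        if (df["end"] < df["start"]).any():
            raise ValueError("probe with end < start")
        self.df = df
        self.regions = tuple(regions)
        self._blocks = self._compute_blocks()

    def _compute_blocks(self) -> list[tuple[str, int, int]]:
        blocks: list[tuple[str, int, int]] = []
        chroms = self.df["chrom"].to_numpy()
        if len(chroms) == 0:
            return blocks
        lo = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[lo]:
                blocks.append((chroms[lo], lo, i - 1))
                lo = i
        return blocks

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_probes(self) -> int:
        return len(self.df)

    @property
    def starts(self) -> np.ndarray:
        return self.df["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.df["end"].to_numpy()

    @property
    def gc(self) -> np.ndarray:
        return self.df["gc"].to_numpy(dtype=float)

    def chrom_blocks(self) -> list[tuple[str, int, int]]:
        """Contiguous per-chromosome index ranges ``(chrom, lo, hi)``, inclusive."""
        return list(self._blocks)

    def probes_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Row indices of probes overlapping ``chrom:start-end`` (1-based closed)."""
        for c, lo, hi in self._blocks:
            if c == str(chrom):
                s = self.df["start"].to_numpy()[lo : hi + 1]
                e = self.df["end"].to_numpy()[lo : hi + 1]
                mask = (e >= start) & (s <= end)
                return np.nonzero(mask)[0] + lo
        return np.array([], dtype=int)


def _simulate_gc(n: int, rng: np.random.Generator) -> np.ndarray:
    return np.clip(rng.normal(0.45, 0.07, size=n), 0.25, 0.70)


def build_design(
    regions: Iterable[RegionSpec | tuple] | None = None,
    backbone_probes: int = DEFAULT_BACKBONE_PROBES,
    backbone_chrom_lengths: dict[str, int] | None = None,
    replicated: tuple[int, int] | None = None,
    gc_seed: int = 20_190_101,
) -> ProbeDesign:
    """Build a probe design from a region table plus a genome-wide backbone.

    Probes of each region are laid down at the region's average spacing,
    starting ``padding`` bp upstream of the locus, so that the requested
    probe count is met exactly.  Backbone probes are spread across all
    autosomes proportionally to chromosome length.

    Parameters
    ----------
    regions:
        Rows of the design table; tuples are coerced to :class:`RegionSpec`.
        ``None`` selects the default HSCR candidate panel.
    backbone_probes:
        Number of genome-wide backbone probes (0 disables the backbone).
    replicated:
        Optional ``(count, fold)``: that many backbone probes are replicated
        ``fold`` times (same probe_id with a replicate suffix), emulating the
        on-chip replication used for QC.
    gc_seed:
        Seed for the simulated per-probe GC fraction (a design property, so
        it is fixed independently of any sample-level seed).
    """
    if regions is None:
        regions = DEFAULT_REGIONS
    specs = [r if isinstance(r, RegionSpec) else RegionSpec(*r) for r in regions]

    rows: list[tuple[str, int, int, str, str]] = []
    for spec in specs:
        count = spec.probe_count
        first = spec.start - spec.padding
        for i in range(count):
            start = first + i * spec.spacing
            end = start + min(PROBE_LEN, spec.spacing) - 1
            safe = re.sub(r"[^0-9A-Za-z]+", "", spec.name)
            rows.append((spec.chrom, start, end, f"{safe}_{i:05d}", spec.name))

    if backbone_probes:
        lengths = backbone_chrom_lengths or CHROM_LENGTHS
        chroms = sorted(lengths, key=chrom_sort_key)
        total = sum(lengths.values())
        counts = {c: int(round(backbone_probes * lengths[c] / total)) for c in chroms}
        # round-off repair so the backbone count is met exactly
        drift = backbone_probes - sum(counts.values())
        for c in chroms:
            if drift == 0:
                break
            counts[c] += 1 if drift > 0 else -1
            drift += -1 if drift > 0 else 1
        k = 0
        for c in chroms:
            n = counts[c]
            if n <= 0:
                continue
            step = lengths[c] // (n + 1)
            for i in range(n):
                start = (i + 1) * step
                rows.append((c, start, start + PROBE_LEN - 1, f"BB_{k:05d}", "backbone"))
                k += 1

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "probe_id", "region"])
    rng = np.random.default_rng(gc_seed)
    df["gc"] = _simulate_gc(len(df), rng)

    if replicated is not None:
        count, fold = replicated
        bb = df.index[df["region"] == "backbone"]
        if count > len(bb):
            raise ValueError("more replicated probes requested than backbone probes")
        chosen = rng.choice(bb.to_numpy(), size=count, replace=False)
        extra = []
        for idx in sorted(chosen):
            base = df.loc[idx]
            for r in range(1, fold):
                row = base.copy()
                row["probe_id"] = f"{base['probe_id']}_r{r}"
                row["region"] = "replicated"
                extra.append(row)
        df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)

    return ProbeDesign(df, specs)
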