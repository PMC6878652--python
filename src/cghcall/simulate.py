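"""Synthetic aCGH data: planted CNVs, noisy profiles, replicates, trios and
population-frequency fixtures.

The generator is the test bed for the whole pipeline: every downstream stage
can be exercised against a known truth without any external download.  Noise
is i.i.d. Gaussian per probe (calibrated so that the measured DLRS matches
the requested ``noise_sd``); an optional linear GC term emulates GC-coupled
wave bias.  Wave/autocorrelated artifacts are deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import ProbeDesign

#: Finite stand-in for log2(0/2) when a homozygous deletion is planted.
DEFAULT_COPY0_FLOOR = -4.0


@dataclass(frozen=True)
class PlantedCNV:
    """Ground-truth container for one simulated copy-number event."""

    chrom: str
    start: int
    end: int
    type: str  # "gain" | "loss"
    copy_number: int
    origin: str | None = None  # "maternal" | "paternal" | "de_novo" | None
    samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.type not in ("gain", "loss"):
            raise ValueError(f"unknown CNV type {self.type!r}")
        if self.type == "loss" and not self.copy_number < 2:
            raise ValueError("loss requires copy_number < 2")
        if self.type == "gain" and not self.copy_number > 2:
            raise ValueError("gain requires copy_number > 2")
        if self.origin not in (None, "maternal", "paternal", "de_novo"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.end < self.start:
            raise ValueError("CNV end < start")

    def shift(self, copy0_floor: float | None = DEFAULT_COPY0_FLOOR) -> float:
        """Expected log2 ratio of probes inside this CNV."""
        if self.copy_number == 0:
            if copy0_floor is None:
                raise ValueError("copy_number 0 needs a finite log2 floor")
            return float(copy0_floor)
        return math.log2(self.copy_number / 2.0)


@dataclass
class SampleProfile:
    """Per-probe log2 ratios of one hybridisation, aligned to a design."""

    sample_id: str
    ratios: np.ndarray
    replicate_group: str | None = None
    expected: np.ndarray | None = None  # simulation truth, when available
    dlrs: float | None = None
    qc_flag: str | None = None  # "pass" | "replicate_required"


@dataclass(frozen=True)
class TrioManifest:
    """Child plus (possibly unavailable) parents.

    Absent parents are recorded as unavailable (``None``), never as
    unaffected members.
    """

    child: str
    mother: str | None
    father: str | None
    affected: tuple[str, ...] = ()  # members affected by the phenotype


def plant_cnvs(
    design: ProbeDesign,
    cnvs: Iterable[PlantedCNV],
    sample: str | None = None,
    copy0_floor: float | None = DEFAULT_COPY0_FLOOR,
) -> np.ndarray:
    """Expected log2 vector for one sample given planted CNVs.

    Probes inside a CNV get ``log2(copy_number/2)`` (copy 0 capped at
    ``copy0_floor``); probes outside get 0.  When ``sample`` is given, only
    CNVs listing it among their carriers are applied.
    """
    expected = np.zeros(design.n_probes)
    for cnv in cnvs:
        if sample is not None and cnv.samples and sample not in cnv.samples:
            continue
        idx = design.probes_in(cnv.chrom, cnv.start, cnv.end)
        if len(idx) == 0:
            raise ValueError(
                f"planted CNV {cnv.chrom}:{cnv.start}-{cnv.end} covers no probe"
            )
        expected[idx] = cnv.shift(copy0_floor)
    return expected


def render_profile(
    design: ProbeDesign,
    expected: np.ndarray,
    noise_sd: float,
    seed: int | np.random.SeedSequence,
    sample_id: str = "sample",
    gc_slope: float = 0.0,
    replicate_group: str | None = None,
) -> SampleProfile:
    """Add Gaussian probe noise (and optional GC-coupled bias) to an expected
    log2 vector, reproducibly for a given seed."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    expected = np.asarray(expected, dtype=float)
    if expected.shape != (design.n_probes,):
        raise ValueError("expected vector does not match design probe count")
    rng = np.random.default_rng(seed)
    ratios = expected + rng.normal(0.0, noise_sd, size=design.n_probes)
    if gc_slope:
        gc = design.gc
        ratios = ratios + gc_slope * (gc - gc.mean())
    return SampleProfile(
        sample_id=sample_id,
        ratios=ratios,
        replicate_group=replicate_group,
        expected=expected.copy(),
    )


def make_replicates(
    design: ProbeDesign,
    profile: SampleProfile,
    k: int,
    noise_sd: float,
    seed: int | np.random.SeedSequence,
    gc_slope: float = 0.0,
) -> list[SampleProfile]:
    """Re-hybridisations of the same sample: same expected vector, fresh noise.

    The returned profiles (and the input profile) share a replicate group
    label so concordance can be evaluated downstream.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if profile.expected is None:
        raise ValueError("profile has no expected vector to replicate")
    group = profile.replicate_group or profile.sample_id
    profile.replicate_group = group
    seq = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    out = []
    for i, child_seq in enumerate(seq.spawn(k), start=1):
        rep = render_profile(
            design,
            profile.expected,
            noise_sd,
            child_seq,
            sample_id=f"{profile.sample_id}_rep{i}",
            gc_slope=gc_slope,
            replicate_group=group,
        )
        out.append(rep)
    return out


def make_population_db(
    entries: Iterable[tuple[str, int, int, str, int, int]],
    source: str,
) -> pd.DataFrame:
    """Population-database fixture emulating DGV/gnomAD/DDD frequency tables.

    ``entries`` are ``(chrom, start, end, type, carriers, cohort)`` rows; the
    stored frequency is ``carriers / cohort``.
    """
    rows = []
    for chrom, start, end, typ, carriers, cohort in entries:
        if cohort <= 0:
            raise ValueError("cohort size must be positive")
        if carriers > cohort:
            raise ValueError("carrier count exceeds cohort size")
        if typ not in ("gain", "loss"):
            raise ValueError(f"unknown CNV type {typ!r}")
        rows.append(
            (str(chrom), int(start), int(end), typ, int(carriers), int(cohort),
             carriers / cohort, source)
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "type", "carriers", "cohort",
                 "frequency", "source"],
    )


# ---------------------------------------------------------------------------
# cohort- and trio-level generators


def _random_cnvs(
    design: ProbeDesign,
    rng: np.random.Generator,
    n_cnvs: int,
    size_range: tuple[int, int],
    gain_copy: int,
    loss_copy: int,
    min_gap_probes: int,
    sample: str,
    origin: str | None = None,
) -> list[PlantedCNV]:
    """Place ``n_cnvs`` non-adjacent CNVs on random probe runs of the design."""
    starts = design.starts
    ends = design.ends
    blocks = design.chrom_blocks()
    taken: list[tuple[int, int]] = []
    cnvs: list[PlantedCNV] = []
    attempts = 0
    while len(cnvs) < n_cnvs and attempts < 2000:
        attempts += 1
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        chrom, lo, hi = blocks[int(rng.integers(len(blocks)))]
        if hi - lo + 1 < size + 2:
            continue
        i = int(rng.integers(lo, hi - size + 2))
        j = i + size - 1
        if any(i - min_gap_probes <= b and a - min_gap_probes <= j for a, b in taken):
            continue
        typ = "gain" if rng.random() < 0.5 else "loss"
        cn = gain_copy if typ == "gain" else loss_copy
        cnvs.append(
            PlantedCNV(chrom, int(starts[i]), int(ends[j]), typ, cn,
                       origin=origin, samples=(sample,))
        )
        taken.append((i, j))
    if len(cnvs) < n_cnvs:
        raise RuntimeError("could not place requested CNVs without overlap")
    return cnvs


def simulate_cohort(
    design: ProbeDesign,
    n_samples: int,
    seed: int,
    n_cnvs_per_sample: int = 3,
    size_range: tuple[int, int] = (2, 15),
    noise_sd: float = 0.15,
    gain_copy: int = 3,
    loss_copy: int = 1,
    gc_slope: float = 0.0,
    min_gap_probes: int = 10,
) -> tuple[list[SampleProfile], list[PlantedCNV]]:
    """A cohort of noisy profiles with per-sample planted CNVs.

    Defaults reflect the study conditions the package targets: a 15K-style
    design, events of 2-15 probes, single-copy gains (+0.585) and losses
    (-1.0), and probe noise at a DLRS of about 0.15.
    """
    seq = np.random.SeedSequence(seed)
    place_rng = np.random.default_rng(seq.spawn(1)[0])
    profiles: list[SampleProfile] = []
    truth: list[PlantedCNV] = []
    sample_seqs = seq.spawn(n_samples)
    for s in range(n_samples):
        sid = f"S{s:03d}"
        cnvs = (
            _random_cnvs(design, place_rng, n_cnvs_per_sample, size_range,
                         gain_copy, loss_copy, min_gap_probes, sid)
            if n_cnvs_per_sample
            else []
        )
        truth.extend(cnvs)
        expected = plant_cnvs(design, cnvs, sample=sid)
        profiles.append(
            render_profile(design, expected, noise_sd, sample_seqs[s],
                           sample_id=sid, gc_slope=gc_slope)
        )
    return profiles, truth


def simulate_trio(
    design: ProbeDesign,
    seed: int | np.random.SeedSequence,
    origin: str = "maternal",
    size_range: tuple[int, int] = (4, 10),
    noise_sd: float = 0.12,
    gain_copy: int = 3,
    loss_copy: int = 1,
    child_id: str = "child",
) -> tuple[TrioManifest, dict[str, SampleProfile], PlantedCNV]:
    """One parent-child trio with a single CNV of known parental origin.

    Inherited CNVs are planted in the child and in exactly one parent; de
    novo CNVs in the child only.
    """
    if origin not in ("maternal", "paternal", "de_novo"):
        raise ValueError(f"unknown origin {origin!r}")
    seq = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    place_seq, c_seq, m_seq, f_seq = seq.spawn(4)
    rng = np.random.default_rng(place_seq)
    mother_id, father_id = f"{child_id}_mo", f"{child_id}_fa"
    carriers = [child_id]
    if origin == "maternal":
        carriers.append(mother_id)
    elif origin == "paternal":
        carriers.append(father_id)
    (cnv,) = _random_cnvs(design, rng, 1, size_range, gain_copy, loss_copy,
                          10, child_id, origin=origin)
    cnv = PlantedCNV(cnv.chrom, cnv.start, cnv.end, cnv.type, cnv.copy_number,
                     origin=origin, samples=tuple(carriers))
    profiles = {}
    for sid, sseq in ((child_id, c_seq), (mother_id, m_seq), (father_id, f_seq)):
        expected = plant_cnvs(design, [cnv], sample=sid)
        profiles[sid] = render_profile(design, expected, noise_sd, sseq,
                                       sample_id=sid)
    manifest = TrioManifest(child=child_id, mother=mother_id, father=father_id,
                            affected=(child_id,))
    return manifest, profiles, cnv
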