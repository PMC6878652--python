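"""Readers and writers for the pipeline's interchange tables.

Everything is tab-separated text.  Each file written by the pipeline
carries ``#``-prefixed header comments recording the tool version, the
configuration hash and the seed, so any output can be traced back to the
exact run that produced it.  Internally all intervals are 1-based fully
closed; BED export (0-based half-open) converts only at this boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .design import ProbeDesign, chrom_sort_key
from .simulate import SampleProfile

MANIFEST_COLUMNS = ["sample_id", "file", "replicate_group", "sex", "hscr_form",
                    "syndromic", "ret_status"]


def _version() -> str:
    from . import __version__

    return __version__


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    """Write a TSV with ``# key: value`` provenance comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# cghcall: {_version()}\n")
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (comments skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# coordinate conversion

def closed_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based closed -> BED 0-based half-open: (100, 200) -> (99, 200)."""
    return start - 1, end


def bed_to_closed(start: int, end: int) -> tuple[int, int]:
    return start + 1, end


# ---------------------------------------------------------------------------
# probe design

def write_design(design: ProbeDesign, path: str | Path,
                 meta: Mapping[str, object] | None = None) -> None:
    write_table(design.df, path, meta)


def read_design(path: str | Path) -> ProbeDesign:
    df = read_table(path, dtype={"chrom": str})
    return ProbeDesign(df)


def design_to_bed(design: ProbeDesign, path: str | Path) -> None:
    """BED6 export of the probe scaffold (name = probe_id, score 0)."""
    rows = []
    for _, p in design.df.iterrows():
        b0, b1 = closed_to_bed(int(p["start"]), int(p["end"]))
        rows.append((p["chrom"], b0, b1, p["probe_id"], 0, "."))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# profiles and manifests

def write_profile(design: ProbeDesign, profile: SampleProfile, path: str | Path,
                  meta: Mapping[str, object] | None = None) -> None:
    df = pd.DataFrame({
        "probe_id": design.df["probe_id"],
        "log2ratio": np.asarray(profile.ratios, dtype=float),
    })
    write_table(df, path, meta)


def read_profile(design: ProbeDesign, path: str | Path,
                 sample_id: str | None = None,
                 replicate_group: str | None = None) -> SampleProfile:
    df = read_table(path)
    if list(df["probe_id"]) != list(design.df["probe_id"]):
        raise ValueError(f"{path}: probe_id column does not match the design")
    return SampleProfile(
        sample_id=sample_id or Path(path).stem,
        ratios=df["log2ratio"].to_numpy(dtype=float),
        replicate_group=replicate_group,
    )


def validate_manifest(df: pd.DataFrame, path: str | Path = "<manifest>") -> pd.DataFrame:
    missing = set(MANIFEST_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing column(s) {sorted(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        lines = [str(i + 2) for i in dup.index]  # +2: header + 1-based
        raise ValueError(
            f"{path}: duplicate sample_id {sorted(set(dup))} at line(s) {', '.join(lines)}"
        )
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    return validate_manifest(read_table(path, dtype={"sample_id": str}), path)


# ---------------------------------------------------------------------------
# calls

def calls_to_bed(calls: pd.DataFrame, path: str | Path,
                 score_cap: float = 1000.0) -> None:
    """Extended BED export of calls: outer interval in BED convention, then
    the extra columns (type, probe_count, malr, inner coords, source)."""
    rows = []
    for _, c in calls.iterrows():
        b0, b1 = closed_to_bed(int(c["outer_start"]), int(c["outer_end"]))
        rows.append((
            c["chrom"], b0, b1, c["sample_id"],
            min(abs(float(c["score"])), score_cap), ".",
            c["type"], int(c["probe_count"]), float(c["malr"]),
            int(c["inner_start"]), int(c["inner_end"]), c["source"],
        ))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def bed_to_calls(path: str | Path) -> pd.DataFrame:
    """Reimport of :func:`calls_to_bed` output (inner/outer both recovered)."""
    names = ["chrom", "bed_start", "bed_end", "sample_id", "score", "strand",
             "type", "probe_count", "malr", "inner_start", "inner_end", "source"]
    df = pd.read_csv(path, sep="\t", header=None, names=names,
                     dtype={"chrom": str})
    outer = [bed_to_closed(int(s), int(e))
             for s, e in zip(df["bed_start"], df["bed_end"])]
    df["outer_start"] = [s for s, _ in outer]
    df["outer_end"] = [e for _, e in outer]
    return df.drop(columns=["bed_start", "bed_end", "strand"])
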