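"""Stage-wise pipeline orchestration over a run directory.

Stages (mirroring the analysis funnel): simulate -> qc -> segment ->
curate -> compare -> classify -> inherit -> report.  Each stage reads its
inputs from, and writes its outputs into, one run directory, so stages
can be re-run individually and whole runs are diffable: identical config
and seed give byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import curate as _curate
from . import popdb as _popdb
from . import qc as _qc
from . import segment as _segment
from . import trio as _trio
from .classify import annotate_truth, cohort_summary, validation_summary
from .config import RunConfig
from .design import ProbeDesign, build_design
from .io import (calls_to_bed, read_design, read_manifest, read_profile,
                 read_table, write_design, write_profile, write_table)
from .simulate import make_replicates, plant_cnvs, simulate_cohort, simulate_trio

log = logging.getLogger("cghcall")

DESIGN_FILE = "design.tsv"
MANIFEST_FILE = "manifest.tsv"
TRUTH_FILE = "truth.tsv"
POPDB_FILE = "popdb.tsv"
TRIO_FILE = "trios.tsv"
QC_FILE = "qc_report.tsv"
CALLS_FILE = "calls.tsv"
CURATED_FILE = "curated.tsv"
MATCHED_FILE = "matched.tsv"
TRUTH_ANNOTATED_FILE = "truth_annotated.tsv"
SUMMARY_FILE = "summary.tsv"
ORIGINS_FILE = "origins.tsv"
REPORT_FILE = "report.txt"


def _meta(cfg: RunConfig) -> dict:
    return {"config_hash": cfg.hash(), "seed": cfg.seed}


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path.name}; run stage '{produced_by}' first"
        )
    return path


def stage_simulate(
    cfg: RunConfig,
    rundir: str | Path,
    n_samples: int = 8,
    n_cnvs_per_sample: int = 3,
    noise_sd: float = 0.15,
    gc_slope: float = 0.0,
    n_replicates: int = 1,
    n_trios: int = 0,
    design: ProbeDesign | None = None,
) -> None:
    """Generate a simulated cohort (plus optional trios) into the run dir."""
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    meta = _meta(cfg)
    if design is None:
        design = build_design()
    write_design(design, rundir / DESIGN_FILE, meta)

    profiles, truth = simulate_cohort(
        design, n_samples, seed=cfg.seed,
        n_cnvs_per_sample=n_cnvs_per_sample, noise_sd=noise_sd,
        gc_slope=gc_slope,
    )
    reps = []
    for i, prof in enumerate(profiles):
        if n_replicates:
            reps.extend(make_replicates(design, prof, n_replicates, noise_sd,
                                        seed=cfg.seed * 100003 + i))
    trio_rows = []
    origins = ("maternal", "paternal", "de_novo")
    trio_seq = np.random.SeedSequence(cfg.seed + 777).spawn(max(n_trios, 1))
    for t in range(n_trios):
        manifest, trio_profiles, cnv = simulate_trio(
            design, trio_seq[t], origin=origins[t % 3],
            noise_sd=noise_sd, child_id=f"T{t:03d}",
        )
        profiles.extend(trio_profiles.values())
        truth.append(cnv)
        trio_rows.append((manifest.child, manifest.mother, manifest.father))

    (rundir / "profiles").mkdir(exist_ok=True)
    manifest_rows = []
    filler = {"sex": "M", "hscr_form": "S", "syndromic": "no",
              "ret_status": "none"}
    for prof in profiles + reps:
        fname = f"profiles/{prof.sample_id}.tsv"
        write_profile(design, prof, rundir / fname, meta)
        manifest_rows.append({
            "sample_id": prof.sample_id, "file": fname,
            "replicate_group": prof.replicate_group or "", **filler,
        })
    write_table(pd.DataFrame(manifest_rows), rundir / MANIFEST_FILE, meta)

    truth_df = pd.DataFrame(
        [(c.chrom, c.start, c.end, c.type, c.copy_number, c.origin or "",
          ",".join(c.samples)) for c in truth],
        columns=["chrom", "start", "end", "type", "copy_number", "origin",
                 "samples"],
    )
    write_table(truth_df, rundir / TRUTH_FILE, meta)
    if trio_rows:
        write_table(pd.DataFrame(trio_rows, columns=["child", "mother", "father"]),
                    rundir / TRIO_FILE, meta)
    log.info("simulate: %d samples, %d replicates, %d trios, %d planted CNVs",
             n_samples, len(reps), n_trios, len(truth_df))


def _load_profiles(rundir: Path, design: ProbeDesign) -> tuple[pd.DataFrame, dict]:
    manifest = read_manifest(rundir / MANIFEST_FILE)
    profiles = {}
    for _, row in manifest.iterrows():
        rep = row.get("replicate_group", "")
        rep = None if (pd.isna(rep) or rep == "") else str(rep)
        profiles[row["sample_id"]] = read_profile(
            design, rundir / row["file"], sample_id=row["sample_id"],
            replicate_group=rep,
        )
    return manifest, profiles


def stage_qc(cfg: RunConfig, rundir: str | Path) -> None:
    """Centralize, GC-correct, compute DLRS and gate every sample."""
    rundir = Path(rundir)
    design = read_design(_require(rundir / DESIGN_FILE, "qc", "simulate"))
    _require(rundir / MANIFEST_FILE, "qc", "simulate")
    manifest, profiles = _load_profiles(rundir, design)
    (rundir / "corrected").mkdir(exist_ok=True)
    rows = []
    for sid, prof in profiles.items():
        _qc.preprocess(design, prof, apply_gc=cfg.qc.gc_correction,
                       dlrs_gate=cfg.qc.dlrs_gate)
        write_profile(design, prof, rundir / "corrected" / f"{sid}.tsv", _meta(cfg))
        rows.append((sid, prof.dlrs, prof.qc_flag))
    write_table(pd.DataFrame(rows, columns=["sample_id", "dlrs", "qc_flag"]),
                rundir / QC_FILE, _meta(cfg))
    log.info("qc: %d samples, %d flagged for replication", len(rows),
             sum(1 for r in rows if r[2] == "replicate_required"))


def _load_corrected(rundir: Path, design: ProbeDesign):
    manifest = read_manifest(rundir / MANIFEST_FILE)
    qc_report = read_table(rundir / QC_FILE).set_index("sample_id")
    profiles = {}
    for _, row in manifest.iterrows():
        sid = row["sample_id"]
        prof = read_profile(design, rundir / "corrected" / f"{sid}.tsv",
                            sample_id=sid)
        rep = row.get("replicate_group", "")
        prof.replicate_group = None if (pd.isna(rep) or rep == "") else str(rep)
        prof.dlrs = float(qc_report.loc[sid, "dlrs"])
        profiles[sid] = prof
    return manifest, profiles


def stage_segment(cfg: RunConfig, rundir: str | Path) -> None:
    """Interval-score detection plus the visual-rescue pass, per sample."""
    rundir = Path(rundir)
    design = read_design(_require(rundir / DESIGN_FILE, "segment", "simulate"))
    _require(rundir / QC_FILE, "segment", "qc")
    manifest, profiles = _load_corrected(rundir, design)
    seg = cfg.segmentation
    frames = []
    for sid, prof in profiles.items():
        sigma = max(prof.dlrs, 1e-6)
        calls = _segment.detect_aberrations(design, prof.ratios, sigma,
                                            threshold=seg.threshold,
                                            sample_id=sid)
        calls = _segment.visual_rescue(
            design, prof.ratios, calls, sigma, sample_id=sid,
            gain_threshold=seg.visual_gain, loss_threshold=seg.visual_loss,
            min_run=seg.visual_min_run,
        )
        frames.append(calls)
    frames = [f for f in frames if len(f)]
    allcalls = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=_segment.CALL_COLUMNS)
    write_table(allcalls, rundir / CALLS_FILE, _meta(cfg))
    calls_to_bed(allcalls, rundir / "calls.bed")
    log.info("segment: %d raw calls (%d visual) in %d samples",
             len(allcalls), int((allcalls["source"] == "visual").sum()),
             len(profiles))


def stage_curate(cfg: RunConfig, rundir: str | Path) -> None:
    """Split/merge, filter, triage, replicate concordance and recurrence."""
    rundir = Path(rundir)
    design = read_design(_require(rundir / DESIGN_FILE, "curate", "simulate"))
    calls = read_table(_require(rundir / CALLS_FILE, "curate", "segment"),
                       dtype={"chrom": str})
    manifest, profiles = _load_corrected(rundir, design)
    cur = cfg.curation
    bands = _curate.TriageBands(
        likely_gain=cur.triage.likely_gain, likely_loss=cur.triage.likely_loss,
        unlikely_malr=cur.triage.unlikely_malr,
        unlikely_two_probe_mean=cur.triage.unlikely_two_probe_mean,
    )
    # replicate arrays confirm their primary sample and are not cohort members
    is_replicate = {
        sid: (p.replicate_group is not None and p.replicate_group != sid)
        for sid, p in profiles.items()
    }
    groups: dict[str, list[str]] = {}
    for sid, p in profiles.items():
        if is_replicate[sid]:
            groups.setdefault(p.replicate_group, []).append(sid)

    curated_frames = []
    calls_by_sample = {sid: grp for sid, grp in calls.groupby("sample_id")}
    for sid, prof in profiles.items():
        sample_calls = calls_by_sample.get(
            sid, pd.DataFrame(columns=_segment.CALL_COLUMNS))
        sigma = max(prof.dlrs, 1e-6)
        curated = _curate.curate_sample(
            design, sample_calls, prof.ratios, sigma,
            malr_min=cur.malr_min, min_probes=cur.min_probes,
            max_gap_probes=cur.max_gap_probes, oppose_ratio=cur.oppose_ratio,
            bands=bands,
        )
        if is_replicate[sid]:
            continue
        rep_ids = groups.get(sid, [])
        rep_calls, rep_ratios = [], []
        for rid in rep_ids:
            rep_calls.append(calls_by_sample.get(
                rid, pd.DataFrame(columns=_segment.CALL_COLUMNS)))
            rep_ratios.append(profiles[rid].ratios)
        statuses = [
            _curate.replicate_concordance(
                design, row, rep_calls, rep_ratios, trend_min=cur.trend_min,
                overlap_min=cfg.matching.overlap_min,
                max_probe_diff=cfg.matching.max_probe_diff,
            )
            for _, row in curated.iterrows()
        ]
        curated["replicate_status"] = statuses
        curated_frames.append(curated)

    columns = _segment.CALL_COLUMNS + ["triage", "replicate_status"]
    curated_frames = [f for f in curated_frames if len(f)]
    curated_all = (pd.concat(curated_frames, ignore_index=True)
                   if curated_frames else pd.DataFrame(columns=columns))
    curated_all["recurrence"] = _curate.compute_recurrence(design, curated_all)
    write_table(curated_all, rundir / CURATED_FILE, _meta(cfg))
    log.info("curate: %d calls retained post-filter", len(curated_all))


def stage_compare(cfg: RunConfig, rundir: str | Path) -> None:
    """Match curated calls against the population-database fixture."""
    rundir = Path(rundir)
    design = read_design(_require(rundir / DESIGN_FILE, "compare", "simulate"))
    curated = read_table(_require(rundir / CURATED_FILE, "compare", "curate"),
                         dtype={"chrom": str})
    db_path = rundir / POPDB_FILE
    db = (read_table(db_path, dtype={"chrom": str}) if db_path.exists()
          else pd.DataFrame(columns=_popdb.DB_COLUMNS))
    m = cfg.matching
    fclasses, dgv_classes, best = [], [], []
    for _, call in curated.iterrows():
        res = _popdb.match(design, call, db,
                           overlap_min=m.overlap_min,
                           max_probe_diff=m.max_probe_diff,
                           compat_ratio=m.compat_ratio, reciprocal=m.reciprocal,
                           common=cfg.frequency.common, rare=cfg.frequency.rare)
        fclasses.append(res.frequency_class)
        dgv = res.matched.loc[res.matched["source"] == "dgv", "frequency"] \
            if len(res.matched) else []
        dgv_classes.append(_popdb.frequency_class(
            dgv, cfg.frequency.common, cfg.frequency.rare))
        best.append(res.best_frequency if res.best_frequency is not None else "")
    curated["frequency_class"] = fclasses
    curated["dgv_class"] = dgv_classes
    curated["best_frequency"] = best
    write_table(curated, rundir / MATCHED_FILE, _meta(cfg))
    log.info("compare: %d calls matched against %d database records",
             len(curated), len(db))


def stage_classify(cfg: RunConfig, rundir: str | Path) -> None:
    """Truth classification and the stratified cohort summary."""
    rundir = Path(rundir)
    matched = read_table(_require(rundir / MATCHED_FILE, "classify", "compare"),
                         dtype={"chrom": str})
    val_path = rundir / "validation.tsv"
    if val_path.exists() and len(matched):
        outcomes = read_table(val_path)
        matched = matched.merge(outcomes, how="left",
                                on=["sample_id", "chrom", "inner_start",
                                    "inner_end"])
    annotated = annotate_truth(matched)
    write_table(annotated, rundir / TRUTH_ANNOTATED_FILE, _meta(cfg))
    manifest = read_manifest(rundir / MANIFEST_FILE)
    primaries = manifest[
        (manifest["replicate_group"].fillna("") == "")
        | (manifest["replicate_group"] == manifest["sample_id"])
    ].copy()
    for col, default in (("sex", "M"), ("hscr_form", "unknown"),
                         ("syndromic", "no"), ("ret_status", "none")):
        if col not in primaries.columns:
            primaries[col] = default
    summary = cohort_summary(annotated, primaries)
    write_table(summary, rundir / SUMMARY_FILE, _meta(cfg))
    log.info("classify: %d true variants (%d novel)",
             int(annotated["is_true"].sum()),
             int((annotated["is_true"] & (annotated["novelty"] == "novel")).sum()))


def stage_inherit(cfg: RunConfig, rundir: str | Path) -> None:
    """Assign parental origin for trio children and test the maternal bias."""
    rundir = Path(rundir)
    trio_path = rundir / TRIO_FILE
    annotated = read_table(
        _require(rundir / TRUTH_ANNOTATED_FILE, "inherit", "classify"),
        dtype={"chrom": str})
    if not trio_path.exists():
        write_table(pd.DataFrame(
            columns=["variant_id", "sample_id", "origin", "mother_evidence",
                     "father_evidence"]), rundir / ORIGINS_FILE, _meta(cfg))
        return
    design = read_design(rundir / DESIGN_FILE)
    trios = read_table(trio_path, dtype=str)
    curated = read_table(rundir / CURATED_FILE, dtype={"chrom": str})
    rows = []
    for _, t in trios.iterrows():
        child = t["child"]
        # prefer truth-supported variants; fall back to all curated calls when
        # no evidence channel exists for the child (pure simulation runs)
        child_calls = annotated[(annotated["sample_id"] == child)
                                & annotated["is_true"]]
        if len(child_calls) == 0:
            child_calls = curated[curated["sample_id"] == child]
        def parent_calls(pid):
            if pd.isna(pid) or pid == "":
                return None
            return curated[curated["sample_id"] == pid]
        mo, fa = parent_calls(t.get("mother")), parent_calls(t.get("father"))
        for i, call in child_calls.iterrows():
            oc = _trio.assign_origin(
                design, call, mo, fa, variant_id=f"{child}:{i}",
                overlap_min=cfg.matching.overlap_min,
                max_probe_diff=cfg.matching.max_probe_diff,
            )
            rows.append((oc.variant_id, child, oc.origin, oc.mother_evidence,
                         oc.father_evidence))
    origins = pd.DataFrame(rows, columns=["variant_id", "sample_id", "origin",
                                          "mother_evidence", "father_evidence"])
    write_table(origins, rundir / ORIGINS_FILE, _meta(cfg))
    log.info("inherit: %d child variants assigned", len(origins))


def transmission_stats(origins: pd.DataFrame, cfg: RunConfig):
    """Maternal-bias test over an origins table (None if nothing inherited)."""
    inherited = origins[origins["origin"].isin(["maternal", "paternal"])]
    if len(inherited) == 0:
        return None
    return _trio.binomial_bias_test(
        int((inherited["origin"] == "maternal").sum()), len(inherited),
        sided=cfg.stats.binomial_sided, alpha=cfg.stats.alpha,
    )


def stage_report(cfg: RunConfig, rundir: str | Path) -> str:
    """Human-readable funnel + stratified summary + transmission line."""
    rundir = Path(rundir)
    _require(rundir / TRUTH_ANNOTATED_FILE, "report", "classify")
    annotated = read_table(rundir / TRUTH_ANNOTATED_FILE, dtype={"chrom": str})
    calls = read_table(rundir / CALLS_FILE, dtype={"chrom": str}) \
        if (rundir / CALLS_FILE).exists() else annotated
    summary = read_table(rundir / SUMMARY_FILE)
    lines = ["# cghcall run report",
             f"config: {cfg.hash()}  seed: {cfg.seed}", "",
             "## funnel"]
    lines.append(f"raw software calls: {int((calls['source'] == 'software').sum())}")
    lines.append(f"visual additions:   {int((calls['source'] == 'visual').sum())}")
    lines.append(f"post-filter calls:  {len(annotated)}")
    n_true = int(annotated["is_true"].sum()) if len(annotated) else 0
    n_novel = int((annotated.get("is_true", pd.Series(dtype=bool))
                   & (annotated.get("novelty", "") == "novel")).sum()) \
        if len(annotated) else 0
    if "selected" in annotated.columns:
        from .classify import count_confirmed

        lines.append(f"confirmed: {count_confirmed(annotated)}")
    lines.append(f"true variants:      {n_true}")
    lines.append(f"novel true:         {n_novel}")
    lines += ["", "## cohort summary (patients)"]
    lines.append(summary.to_string(index=False))
    origins_path = rundir / ORIGINS_FILE
    if origins_path.exists():
        origins = read_table(origins_path)
        t = transmission_stats(origins, cfg)
        if t is not None:
            lines += ["", "## parental origin"]
            pct = 100.0 * t.n_maternal / t.n_inherited
            lines.append(
                f"maternal transmission: {t.n_maternal}/{t.n_inherited} "
                f"({pct:.1f}%), p = {t.p_value:.4f} "
                f"(95% CI {100 * t.ci_low:.1f}-{100 * t.ci_high:.1f}%)"
            )
    text = "\n".join(lines) + "\n"
    (rundir / REPORT_FILE).write_text(text)
    return text


STAGES = {
    "qc": stage_qc,
    "segment": stage_segment,
    "curate": stage_curate,
    "compare": stage_compare,
    "classify": stage_classify,
    "inherit": stage_inherit,
}


def run_pipeline(
    cfg: RunConfig,
    rundir: str | Path,
    simulate: bool = True,
    **simulate_kwargs,
) -> str:
    """Run every stage in order and return the final report text."""
    if simulate:
        stage_simulate(cfg, rundir, **simulate_kwargs)
    for stage in STAGES.values():
        stage(cfg, rundir)
    return stage_report(cfg, rundir)
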