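"""End-to-end orchestration: scan -> context -> (search, conservation, shifts).

The pipeline reads a protein FASTA, scans every record with the configured
motif pattern, classifies each hit's sequence context against the
three-feature signature, optionally runs the iterative profile search, the
alignment conservation contrast and the helicity analysis, and writes a
deterministic plain-text report:

* ``report.tsv`` — one row per candidate hit with coordinates, pattern flags,
  context signature and final tier,
* ``summary.json`` — run-level counts plus the conservation and helicity
  results when their inputs were supplied,
* ``config.json`` — the configuration actually used, verbatim,
* ``tracks/<id>.tsv`` — per-sequence composition/proxy tracks for plotting,
* ``run.log`` — stage log (no timestamps, so identical runs are identical).

Candidate tiers: ``validated-context`` (core match whose context signature
holds), ``context-mismatch`` (core match whose signature fails — the
false-positive outcome), ``search-only`` (profile hit without a core match).

One global seed fans out to per-stage seeds by fixed offsets (+1000 for the
profile search, +2000 for the conservation permutations), so each stage can
be rerun in isolation reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import context_profile, conservation, motif_scan, nmr_helicity, \
    profile_search, sequence_io
from .context_profile import ContextSignature, ContextThresholds

__all__ = [
    "PipelineConfig",
    "CandidateReport",
    "PipelineStageError",
    "STAGE_EXIT_CODES",
    "run_pipeline",
]

SEARCH_SEED_OFFSET = 1000
CONSERVATION_SEED_OFFSET = 2000

STAGE_EXIT_CODES = {
    "sequence_io": 2,
    "motif_scan": 3,
    "profile_search": 4,
    "context_profile": 5,
    "conservation": 6,
    "nmr_helicity": 7,
    "report": 8,
}


class PipelineStageError(RuntimeError):
    """An error surfaced from a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline knobs, each with a documented default."""

    pattern: str = "core"                 # scan pattern: name or bracket syntax
    run_profile_search: bool = False      # also run the iterative PSSM search
    flank: int = 5                        # seed flank length for the search
    evalue_cutoff: float = 1e-3           # empirical E-value cutoff
    max_iterations: int = 5               # iterative search rounds
    exclude_taxa: tuple = ()              # taxa removed before searching
    permutations: int = 1000              # conservation permutation count
    motif_columns: tuple = ()             # 1-based MSA columns of the motif
    flank_columns: tuple = ()             # 1-based MSA flank columns
    residue_policy: str = "strict"        # FASTA non-canonical residue policy
    thresholds: ContextThresholds = field(default_factory=ContextThresholds)
    rng_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        for key in ("exclude_taxa", "motif_columns", "flank_columns"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "thresholds" in data and isinstance(data["thresholds"], dict):
            data["thresholds"] = ContextThresholds(**data["thresholds"])
        for key in ("exclude_taxa", "motif_columns", "flank_columns"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass(frozen=True)
class CandidateReport:
    """One candidate motif occurrence with its evaluation."""

    sequence_id: str
    taxon: Optional[str]
    start: int
    end: int
    span: str
    matches_core: bool
    matches_strict: bool
    matches_phi: bool
    profile_score: Optional[float]
    profile_evalue: Optional[float]
    signature: Optional[ContextSignature]
    tier: str


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


def _candidate_rows(reports: Sequence[CandidateReport]) -> pd.DataFrame:
    rows = []
    for c in reports:
        sig = c.signature
        rows.append({
            "sequence_id": c.sequence_id,
            "taxon": c.taxon or "",
            "start": c.start,
            "end": c.end,
            "span": c.span,
            "matches_core": c.matches_core,
            "matches_strict": c.matches_strict,
            "matches_phi": c.matches_phi,
            "profile_score": "" if c.profile_score is None else f"{c.profile_score:.4f}",
            "profile_evalue": "" if c.profile_evalue is None else f"{c.profile_evalue:.3e}",
            "order_dip": "" if sig is None else sig.order_dip,
            "dip_depth": "" if sig is None else f"{sig.dip_depth:.4f}",
            "idr_context": "" if sig is None else sig.idr_context,
            "idr_length": "" if sig is None else sig.idr_length,
            "net_charge_positive": "" if sig is None else sig.net_charge_positive,
            "mean_rk_de": "" if sig is None else f"{sig.mean_rk_de:.4f}",
            "flank_bias": "" if sig is None else sig.flank_bias,
            "mean_pst_rk": "" if sig is None else f"{sig.mean_pst_rk:.4f}",
            "overall_call": "" if sig is None else sig.overall_call,
            "tier": c.tier,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["sequence_id", "start"], kind="mergesort")
    return df


def run_pipeline(config: PipelineConfig, fasta: Path, msa: Optional[Path] = None,
                 shifts: Optional[Path] = None, out_dir: Optional[Path] = None,
                 ) -> list[CandidateReport]:
    """Run the full analysis; write report files when ``out_dir`` is given.

    Deterministic for a fixed config seed: running twice with identical inputs
    produces byte-identical reports.  Any stage failure is raised as
    :class:`PipelineStageError` naming the stage; an output directory touched
    by a failed run is marked with an ``INCOMPLETE`` file.
    """
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    out_path = Path(out_dir) if out_dir is not None else None
    incomplete_marker = None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        incomplete_marker = out_path / "INCOMPLETE"
        incomplete_marker.write_text("run in progress\n")

    reports, summary, track_frames = _run_stages(
        config, Path(fasta), Path(msa) if msa else None,
        Path(shifts) if shifts else None, log)
    if out_path is not None:
        with _stage("report"):
            _write_outputs(out_path, config, reports, summary, track_frames,
                           log_lines)
        incomplete_marker.unlink()
    return reports


def _run_stages(config, fasta, msa, shifts, log):
    with _stage("sequence_io"):
        records = sequence_io.read_fasta(fasta, policy=config.residue_policy)
        if not records:
            raise ValueError(f"no sequence records in {fasta}")
        log(f"sequence_io: read {len(records)} record(s) from {fasta.name}")

    with _stage("motif_scan"):
        pattern = motif_scan.get_pattern(config.pattern)
        core, strict, phi = motif_scan.builtin_patterns()
        hits = []
        for rec in records:
            hits.extend(motif_scan.scan(rec, pattern))
        log(f"motif_scan: {len(hits)} hit(s) with pattern {pattern.name!r}")

    profile_hits = {}
    if config.run_profile_search:
        with _stage("profile_search"):
            strict_hits = [h for rec in records for h in motif_scan.scan(rec, strict)]
            seed_hits = strict_hits or hits
            if not seed_hits:
                raise ValueError("no motif hits available to seed the profile search")
            seed = profile_search.build_seed(records, seed_hits, config.flank)
            background = profile_search.database_background(records)
            model = profile_search.estimate_profile(seed, background=background)
            found = profile_search.search(
                records, model, exclude_taxa=config.exclude_taxa,
                evalue_cutoff=config.evalue_cutoff,
                max_iterations=config.max_iterations,
                seed_rng=(config.rng_seed + SEARCH_SEED_OFFSET) % (2 ** 31))
            profile_hits = {(h.sequence_id, h.start): h for h in found}
            log(f"profile_search: {len(found)} significant window(s)")

    with _stage("context_profile"):
        by_id = {r.identifier: r for r in records}
        tracks = {}
        track_frames = {}
        for rec in sorted({h.sequence_id for h in hits}):
            t = context_profile.context_tracks(by_id[rec], config.thresholds)
            tracks[rec] = t
            track_frames[rec] = pd.DataFrame({
                "position": range(1, len(by_id[rec].residues) + 1),
                "residue": list(by_id[rec].residues),
                "disorder_proxy": t["proxy"].values.round(6),
                "local_proxy": t["local_proxy"].values.round(6),
                "rk_de": t["rk_de"].values.round(6),
                "pst_rk": t["pst_rk"].values.round(6),
            })
        reports = []
        for hit in hits:
            t = tracks[hit.sequence_id]
            sig = context_profile.classify_context(
                by_id[hit.sequence_id], hit, proxy=t["proxy"],
                local_proxy=t["local_proxy"], rk_de=t["rk_de"],
                pst_rk=t["pst_rk"], thresholds=config.thresholds)
            rec = by_id[hit.sequence_id]
            span = hit.matched_span
            pstart = None
            # Profile hit covering this motif (window start within flank reach).
            score = evalue = None
            for (sid, start), ph in profile_hits.items():
                length = 6 + 2 * config.flank
                if sid == hit.sequence_id and start <= hit.start \
                        and hit.end <= start + length - 1:
                    score, evalue = ph.score, ph.evalue
                    break
            tier = "validated-context" if sig.overall_call else "context-mismatch"
            reports.append(CandidateReport(
                sequence_id=hit.sequence_id, taxon=rec.taxon, start=hit.start,
                end=hit.end, span=span,
                matches_core=bool(motif_scan.get_pattern("core").matches(span)),
                matches_strict=bool(strict.matches(span)),
                matches_phi=bool(phi.matches(span)),
                profile_score=score, profile_evalue=evalue,
                signature=sig, tier=tier))
        covered = {(c.sequence_id, c.start) for c in reports}
        for (sid, start), ph in sorted(profile_hits.items()):
            length = 6 + 2 * config.flank
            overlaps = any(c.sequence_id == sid and start <= c.start
                           and c.end <= start + length - 1 for c in reports)
            if not overlaps:
                rec = by_id[sid]
                reports.append(CandidateReport(
                    sequence_id=sid, taxon=rec.taxon, start=start,
                    end=start + length - 1,
                    span=rec.residues[start - 1:start - 1 + length],
                    matches_core=False, matches_strict=False, matches_phi=False,
                    profile_score=ph.score, profile_evalue=ph.evalue,
                    signature=None, tier="search-only"))
        log(f"context_profile: {len(reports)} candidate(s) classified")

    summary: dict = {
        "n_records": len(records),
        "n_candidates": len(reports),
        "tiers": {tier: sum(1 for c in reports if c.tier == tier)
                  for tier in ("validated-context", "context-mismatch",
                               "search-only")},
    }

    if msa is not None:
        with _stage("conservation"):
            aln = sequence_io.read_alignment(msa, policy=config.residue_policy)
            if not config.motif_columns or not config.flank_columns:
                raise ValueError("conservation requires motif_columns and "
                                 "flank_columns in the configuration")
            contrast = conservation.motif_flank_contrast(
                aln,
                [c - 1 for c in config.motif_columns],
                [c - 1 for c in config.flank_columns],
                permutations=config.permutations,
                seed_rng=(config.rng_seed + CONSERVATION_SEED_OFFSET) % (2 ** 31))
            summary["conservation"] = {
                "motif_mean": round(contrast.motif_mean, 6),
                "flank_mean": round(contrast.flank_mean, 6),
                "contrast": round(contrast.contrast, 6),
                "permutation_p": round(contrast.permutation_p, 6),
            }
            log(f"conservation: contrast={contrast.contrast:.4f} "
                f"p={contrast.permutation_p:.4g}")

    if shifts is not None:
        with _stage("nmr_helicity"):
            table = sequence_io.read_shift_table(shifts)
            profile = nmr_helicity.scs_profile(table)
            estimate = nmr_helicity.helicity(profile)
            summary["helicity"] = {
                "peak_scs_ppm": round(estimate.peak_scs_ppm, 6),
                "fractional_helicity": round(estimate.fractional_helicity, 6),
                "helix_segment": list(estimate.helix_segment)
                if estimate.helix_segment else None,
            }
            log(f"nmr_helicity: peak SCS {estimate.peak_scs_ppm:.3f} ppm, "
                f"helicity {estimate.fractional_helicity:.3f}")

    return reports, summary, track_frames


def _write_outputs(out_path: Path, config: PipelineConfig,
                   reports: Sequence[CandidateReport], summary: dict,
                   track_frames: dict, log_lines: list) -> None:
    df = _candidate_rows(reports)
    df.to_csv(out_path / "report.tsv", sep="\t", index=False)
    tracks_dir = out_path / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for seq_id in sorted(track_frames):
        track_frames[seq_id].to_csv(tracks_dir / f"{seq_id}.tsv", sep="\t",
                                    index=False)
    config_json = json.dumps(config.to_dict(), indent=2, sort_keys=True)
    (out_path / "config.json").write_text(config_json + "\n")
    summary = dict(summary)
    summary["config_sha256"] = hashlib.sha256(config_json.encode()).hexdigest()
    summary["rng_seed"] = config.rng_seed
    (out_path / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (out_path / "run.log").write_text("".join(line + "\n" for line in log_lines))
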