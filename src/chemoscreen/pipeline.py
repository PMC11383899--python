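"""Pipeline configuration and staged execution.

Stage order follows the analysis flow: migration calling, secretome
presence contrast, correlation screen, candidate selection, signature
scoring. Each stage reads and writes files in a result directory, is
individually re-runnable, and is skipped when its outputs are newer than
its inputs. A manifest records the package version, configuration and
seed of each run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .association import screen, select_candidates
from .errors import AnalysisError, ParseError
from .migration import AttractantClass, mean_absolute_counts, summarize_experiment
from .secretome import detected_proteins, presence_contrast
from .signatures import compare_response, resolve_composites, score
from .stats import TestResult

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

_ENUMS = {
    "fdr_family": ("per_subset", "global"),
    "donor_pooling": ("mean", "separate"),
    "score_method": ("mean_z",),
    "lod_floor": ("lod", "half_lod", "raw"),
}


@dataclass
class PipelineConfig:
    """Thresholds and modes for a full pipeline run."""

    ratio_cutoff: float = 2.5
    sd_multiplier: float = 2.0
    alpha: float = 0.05
    majority_threshold: float = 0.5
    fdr_family: str = "per_subset"
    donor_pooling: str = "mean"
    score_method: str = "mean_z"
    lod_floor: str = "lod"
    anchor_subset: str = "cDC1"
    min_detected_samples: int = 1
    use_corrected: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ParseError(f"alpha {self.alpha} outside (0, 1]")
        if not 0.0 <= self.majority_threshold < 1.0:
            raise ParseError(f"majority_threshold {self.majority_threshold} outside [0, 1)")
        if self.ratio_cutoff < 0 or self.sd_multiplier < 0:
            raise ParseError("ratio_cutoff and sd_multiplier must be nonnegative")
        for name, allowed in _ENUMS.items():
            if getattr(self, name) not in allowed:
                raise ParseError(f"{name} must be one of {allowed}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except FileNotFoundError as exc:
            raise ParseError(f"{path}: file not found") from exc
        except yaml.YAMLError as exc:
            raise ParseError(f"{path}: invalid YAML: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _mtime(path: Path) -> float:
    return path.stat().st_mtime


def _stale(outputs: list[Path], inputs: list[Path]) -> bool:
    if any(not o.exists() for o in outputs):
        return True
    newest_input = max((_mtime(p) for p in inputs if p.exists()), default=0.0)
    return min(_mtime(o) for o in outputs) < newest_input


def stage_migration_call(cfg: PipelineConfig, data: Path, out: Path) -> None:
    wells = io.read_wells(data / "wells.csv")
    meta_path = data / "meta.csv"
    meta = io.read_meta(meta_path) if meta_path.exists() else None
    calls = summarize_experiment(
        wells,
        meta,
        ratio_cutoff=cfg.ratio_cutoff,
        sd_multiplier=cfg.sd_multiplier,
        donor_pooling=cfg.donor_pooling,
    )
    io.write_table(calls, out / "calls.tsv")
    counts = mean_absolute_counts(wells, attractant_class=None)
    counts.insert(0, "attractant_id", counts.index)
    io.write_table(counts, out / "mean_counts.tsv")


def stage_secretome_screen(cfg: PipelineConfig, data: Path, out: Path) -> None:
    profiles = io.read_npx(data / "npx.csv", data / "lod.csv")
    cl = [p for p in profiles if p.source == "cell_line"]
    tme = [p for p in profiles if p.source == "tme"]
    if not cl or not tme:
        raise AnalysisError("secretome screen needs both cell-line and TME profiles")
    rows = []
    for protein in profiles[0].panel:
        c = presence_contrast(protein, cl, tme, cfg.majority_threshold)
        rows.append(dataclasses.asdict(c))
    io.write_table(pd.DataFrame(rows), out / "contrasts.tsv")


def stage_screen(cfg: PipelineConfig, data: Path, out: Path) -> None:
    profiles = io.read_npx(data / "npx.csv", data / "lod.csv")
    lod = io.read_lod(data / "lod.csv")
    counts = pd.read_csv(out / "mean_counts.tsv", sep="\t").set_index("attractant_id")
    tme = [p for p in profiles if p.source == "tme"]
    tme_ids = {p.sample_id for p in tme}
    counts = counts.loc[[i for i in counts.index if i in tme_ids]]
    recs = screen(
        counts,
        tme,
        alpha=cfg.alpha,
        lod=lod,
        fdr_family=cfg.fdr_family,
        use_corrected=cfg.use_corrected,
    )
    io.write_table(recs, out / "associations.tsv")


def stage_select(cfg: PipelineConfig, data: Path, out: Path) -> None:
    recs = pd.read_csv(out / "associations.tsv", sep="\t")
    contrasts = pd.read_csv(out / "contrasts.tsv", sep="\t")
    sel = select_candidates(recs, contrasts, cfg.anchor_subset)
    io.write_table(
        pd.DataFrame(
            {
                "protein": list(sel.significant_positive),
                "candidate": [p in set(sel.candidates) for p in sel.significant_positive],
            }
        ),
        out / "candidates.tsv",
    )


def stage_signature_score(cfg: PipelineConfig, data: Path, out: Path) -> None:
    matrix = io.read_expression(data / "expr.csv", data / "labels.csv")
    sigs = io.read_gmt(data / "sigs.gmt")
    comp_path = data / "composites.tsv"
    if comp_path.exists():
        from .signatures import SignatureDef

        composites = io.read_composites(comp_path)
        sigs = sigs + [SignatureDef(n, (), c) for n, c in composites.items()]
    resolved = resolve_composites(sigs)
    score_rows, test_rows = [], []
    for name, sig in resolved.items():
        scores = score(matrix, sig)
        score_rows += [dataclasses.asdict(s) for s in scores]
        if matrix.labels:
            res = compare_response(scores, matrix.labels)
            test_rows.append({"signature": name, **res.as_record()})
    io.write_table(pd.DataFrame(score_rows), out / "scores.tsv")
    if test_rows:
        io.write_table(pd.DataFrame(test_rows), out / "signature_tests.tsv")


#: stage name -> (runner, input files, output files)
STAGES: dict[str, tuple] = {
    "migration-call": (
        stage_migration_call,
        ["wells.csv", "meta.csv"],
        ["calls.tsv", "mean_counts.tsv"],
    ),
    "secretome-screen": (stage_secretome_screen, ["npx.csv", "lod.csv"], ["contrasts.tsv"]),
    "screen": (stage_screen, ["npx.csv", "lod.csv", "mean_counts.tsv"], ["associations.tsv"]),
    "select": (stage_select, ["associations.tsv", "contrasts.tsv"], ["candidates.tsv"]),
    "signature-score": (
        stage_signature_score,
        ["expr.csv", "sigs.gmt", "labels.csv"],
        ["scores.tsv", "signature_tests.tsv"],
    ),
}


def run_pipeline(
    config: PipelineConfig,
    data_dir: str | Path,
    out_dir: str | Path,
    force: bool = False,
    log=print,
) -> Path:
    """Run all stages, skipping those whose outputs are up to date."""
    data, out = Path(data_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, (runner, inputs, outputs) in STAGES.items():
        # Raw inputs live in the data directory, intermediates in the result
        # directory.
        in_paths = [data / f if (data / f).exists() else out / f for f in inputs]
        out_paths = [out / f for f in outputs]
        if name == "signature-score" and not (data / "expr.csv").exists():
            log(f"[{name}] skipped: no expression data")
            continue
        if not force and not _stale(out_paths, in_paths):
            log(f"[{name}] up to date")
            continue
        log(f"[{name}] running")
        try:
            runner(config, data, out)
        except (ParseError, AnalysisError) as exc:
            raise type(exc)(f"stage {name!r}: {exc}") from exc
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "package": "chemoscreen",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
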