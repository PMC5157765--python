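"""End-to-end pipeline: simulate -> ingest -> summarize -> timeseries -> granger.

One structured YAML config drives a reproducible run; every artifact
written is listed in a manifest with content hashes so identical
config + seed gives an identical manifest.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .descriptives import category_overlap, summarize, top_k_table
from .granger import run_paper_design
from .ingest import ingest
from .synthetic import SimulationConfig, preset_config, write_dataset
from .timeseries import monthly_counts, plot_series, prr_series
from .vocab import TermHierarchy, default_vocabulary

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    outdir: Path
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # preset + SimulationConfig overrides
    reviews_csv: Path | None = None  # alternatively, pre-existing inputs
    reports_csv: Path | None = None
    lexicon_csv: Path | None = None
    hierarchy_csv: Path | None = None
    specific_ae: str = "cardiac"
    top_k: int = 20
    level: str = "hlt"
    include_trial_literature: bool = False
    prr: bool = True
    max_lag: int = 12
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(
            outdir=Path(raw.get("outdir", "aelead_out")),
            seed=int(raw.get("seed", 0)),
            simulate=raw.get("simulate", {}) or {},
            reviews_csv=Path(raw["reviews_csv"]) if raw.get("reviews_csv") else None,
            reports_csv=Path(raw["reports_csv"]) if raw.get("reports_csv") else None,
            lexicon_csv=Path(raw["lexicon_csv"]) if raw.get("lexicon_csv") else None,
            hierarchy_csv=Path(raw["hierarchy_csv"]) if raw.get("hierarchy_csv") else None,
            specific_ae=raw.get("specific_ae", "cardiac"),
            top_k=int(raw.get("top_k", 20)),
            level=raw.get("level", "hlt"),
            include_trial_literature=bool(raw.get("include_trial_literature", False)),
            prr=bool(raw.get("prr", True)),
            max_lag=int(raw.get("max_lag", 12)),
            log_level=raw.get("log_level", "INFO"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if self.level not in ("hlt", "hlgt"):
            raise ValueError("level must be 'hlt' or 'hlgt'")
        for name in ("reviews_csv", "reports_csv", "lexicon_csv", "hierarchy_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if not self.simulate and (self.reviews_csv is None or self.reports_csv is None):
            raise ValueError("either a simulate block or both input CSVs are required")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = {k: str(v) for k, v in vars(config).items()}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the artifact manifest."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str) -> Path:
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(path)
        return path

    # -- stage 1: inputs --------------------------------------------------
    stage = "simulate"
    try:
        if config.simulate:
            sim = dict(config.simulate)
            drug = sim.pop("preset", sim.pop("drug", "sibutramine"))
            sim.setdefault("seed", config.seed)
            sim_config = preset_config(drug, **sim)
            paths = write_dataset(sim_config, outdir)
            written.extend(paths.values())
            reviews_csv, reports_csv = paths["reviews"], paths["reports"]
        else:
            drug = None
            reviews_csv, reports_csv = config.reviews_csv, config.reports_csv

        # -- stage 2: ingest ----------------------------------------------
        stage = "ingest"
        if config.lexicon_csv is not None and config.hierarchy_csv is not None:
            vocab = TermHierarchy.from_files(
                config.hierarchy_csv, config.lexicon_csv, drug=drug
            )
        else:
            probe = pd.read_csv(reviews_csv, nrows=1)
            drug = drug or str(probe["drug"].iloc[0])
            vocab = default_vocabulary(drug)
        sm, reg = ingest(
            reviews_csv, reports_csv, vocab,
            include_trial_literature=config.include_trial_literature,
            level=config.level,
        )
        _write(sm.exclusions, "exclusions_social_media.csv")
        _write(reg.exclusions, "exclusions_regulatory.csv")

        # -- stage 3: descriptives -----------------------------------------
        stage = "summarize"
        specific = config.specific_ae if config.specific_ae in vocab.specific else next(iter(vocab.specific), None)
        if specific is None:
            raise ValueError("vocabulary defines no specific-AE filters")
        summary = summarize(sm, reg, specific)
        _write(summary.per_stream, "summary_per_stream.csv")
        _write(summary.comparisons, "summary_comparisons.csv")
        top_sm = top_k_table(sm, config.top_k)
        top_reg = top_k_table(reg, config.top_k)
        _write(top_sm.table, "top_k_social_media.csv")
        _write(top_reg.table, "top_k_regulatory.csv")
        overlap = category_overlap(top_sm, top_reg, vocab.category_map)
        conc = pd.DataFrame(
            [
                {"stream": "social_media", **{f"concentration_{k}": v for k, v in top_sm.concentration.items()}, "overlap_with_other_stream": overlap},
                {"stream": "regulatory", **{f"concentration_{k}": v for k, v in top_reg.concentration.items()}, "overlap_with_other_stream": overlap},
            ]
        )
        _write(conc, "concentration_overlap.csv")

        # -- stage 4: time series ------------------------------------------
        stage = "timeseries"
        sm_counts = monthly_counts(sm, "all")
        reg_counts = monthly_counts(reg, "all")
        start = min(sm_counts.start, reg_counts.start)
        end = max(sm_counts.end, reg_counts.end)
        sm_counts = sm_counts.align_to(start, end)
        reg_counts = reg_counts.align_to(start, end)
        series_frames = [sm_counts.to_frame(), reg_counts.to_frame()]
        sm_spec = monthly_counts(sm, specific, span=(start, end), clip=False)
        reg_spec = monthly_counts(reg, specific, span=(start, end), clip=False)
        series_frames += [sm_spec.to_frame(), reg_spec.to_frame()]
        _write(pd.concat(series_frames, ignore_index=True), "monthly_counts.csv")
        fig_path = outdir / "timeseries.png"
        plot_series(sm_counts, reg_counts, fig_path)
        written.append(fig_path)
        prr = None
        if config.prr:
            prr = prr_series(reg, specific)
            _write(prr.table.assign(month=prr.table["month"].astype(str)), "prr_series.csv")

        # -- stage 5: granger ----------------------------------------------
        stage = "granger"
        report = run_paper_design(
            sm_counts, reg_counts, sm_spec, reg_spec,
            max_lag=config.max_lag, labels=("all", specific),
        )
        if prr is not None:
            vals = prr.values.to_numpy()
            if not pd.isna(vals).any():
                prr_row = run_paper_design(
                    sm_spec, vals, max_lag=config.max_lag, labels=(f"prr_{specific}",)
                )
                report = pd.concat([report, prr_row], ignore_index=True)
            else:
                logger.warning("PRR series has undefined months; PRR sensitivity VAR skipped")
        _write(report, "granger_report.csv")
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "artifacts": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
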