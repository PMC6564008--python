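"""Result serialization: per-replicate CSV, daily quantile CSV, run manifest."""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .simulate import EnsembleResult, SimulationConfig

__all__ = ["RunManifest", "write_results", "read_summary"]

REPLICATE_CSV = "replicates.csv"
DAILY_CSV = "daily_quantiles.csv"
MANIFEST_JSON = "manifest.json"
SUMMARY_JSON = "summary.json"


@dataclass
class RunManifest:
    """Provenance record written alongside every result set."""

    seed: int | None
    config: dict
    temperature_source: str
    package_version: str = __version__
    timestamp: str = field(default_factory=lambda: dt.datetime.now().isoformat(timespec="seconds"))
    outputs: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def _config_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["start_date"] = cfg.start_date.isoformat()
    return d


def write_results(
    result: EnsembleResult,
    outdir: str | Path,
    temperature_source: str = "unknown",
) -> dict[str, Path]:
    """Write an ensemble to ``outdir``: replicate summaries, daily quantile
    bands, a scalar summary, and a manifest recording seed/config/version.

    Column order is stable; the replicate CSV round-trips through
    :func:`read_summary`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "replicates": outdir / REPLICATE_CSV,
        "daily": outdir / DAILY_CSV,
        "summary": outdir / SUMMARY_JSON,
        "manifest": outdir / MANIFEST_JSON,
    }
    result.to_replicate_frame().to_csv(paths["replicates"], index=False)
    result.daily.to_csv(paths["daily"], index=False)
    paths["summary"].write_text(json.dumps(result.summary(), indent=2))
    manifest = RunManifest(
        seed=result.config.seed,
        config=_config_dict(result.config),
        temperature_source=temperature_source,
        outputs=[p.name for p in paths.values()],
    )
    paths["manifest"].write_text(manifest.to_json())
    return paths


def read_summary(outdir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Read back (replicate frame, daily frame, manifest dict) from ``outdir``."""
    outdir = Path(outdir)
    reps = pd.read_csv(outdir / REPLICATE_CSV)
    daily = pd.read_csv(outdir / DAILY_CSV)
    manifest = json.loads((outdir / MANIFEST_JSON).read_text())
    return reps, daily, manifest
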