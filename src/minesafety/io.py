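"""Output writing: trajectory/summary CSVs, ranking JSON, run manifest."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import __version__
from .scenarios import InfluenceRanking
from .sd_engine import Trajectory

__all__ = ["write_outputs"]


def write_outputs(
    trajectories: Mapping[str, Trajectory] | None = None,
    summaries: Optional[pd.DataFrame] = None,
    rankings: Mapping[str, InfluenceRanking] | None = None,
    out_dir="runs",
    config_echo: Optional[dict] = None,
    seed: Optional[int] = None,
) -> dict:
    """Write run outputs and a manifest; returns the manifest.

    Trajectories go to ``trajectory_<label>.csv`` (6-decimal fixed point, so
    repeated deterministic runs are byte-identical), summaries to
    ``summary.csv``, rankings to ``ranking_<label>.json``, and the manifest —
    package version, seed, config echo, file list — to ``manifest.json``.
    Raises ``ValueError`` if there is nothing to write.
    """
    trajectories = dict(trajectories or {})
    rankings = dict(rankings or {})
    if not trajectories and summaries is None and not rankings:
        raise ValueError("nothing to write: all outputs empty")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    for label, traj in trajectories.items():
        name = f"trajectory_{label}.csv"
        traj.to_csv(out / name)
        files.append(name)
    if summaries is not None:
        summaries.to_csv(out / "summary.csv", index=False,
                         float_format="%.6f")
        files.append("summary.csv")
    for label, ranking in rankings.items():
        name = f"ranking_{label}.json"
        ranking.to_json(out / name)
        files.append(name)

    manifest = {
        "package": "minesafety",
        "version": __version__,
        "seed": seed,
        "config": config_echo or {},
        "files": files,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
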