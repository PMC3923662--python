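"""Tidy-format result serialization used by the CLI and the scripts."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .protocols import GroupResult

__all__ = ["engagement_frame", "rpe_frame", "dose_response_frame", "write_results"]


def engagement_frame(results: dict[str, GroupResult]) -> pd.DataFrame:
    """One row per group x block x stimulus: probability and s.e.m."""
    rows = []
    for label, res in results.items():
        for stimulus in ("lever", "magazine"):
            mean, sem = res.engagement_curve(stimulus)
            for b, (m, s) in enumerate(zip(mean, sem)):
                rows.append({
                    "group": label, "n_agents": res.lever.shape[0], "block": b,
                    "stimulus": stimulus, "probability": m, "sem": s,
                })
    return pd.DataFrame(rows)


def rpe_frame(results: dict[str, GroupResult]) -> pd.DataFrame:
    """One row per group x session x event: mean RPE and s.e.m."""
    rows = []
    for label, res in results.items():
        for event in ("CS", "US"):
            mean, sem = res.rpe_curve(event)
            for sess, (m, s) in enumerate(zip(mean, sem)):
                rows.append({
                    "group": label, "session": sess, "event": event,
                    "mean_delta": m, "sem": s,
                })
    return pd.DataFrame(rows)


def dose_response_frame(dose_response: dict[float, dict[str, float]]) -> pd.DataFrame:
    rows = [
        {"dose": dose, "measure": measure, "probability": p}
        for dose, measures in dose_response.items()
        for measure, p in measures.items()
    ]
    return pd.DataFrame(rows)


def write_results(outdir: str | Path, *, frames: dict[str, pd.DataFrame] | None = None,
                  summary: dict | None = None, config: dict | None = None) -> None:
    """Write CSV frames, a JSON summary, and the resolved configuration."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in (frames or {}).items():
        frame.to_csv(out / f"{name}.csv", index=False, float_format="%.6f")
    if summary is not None:
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    if config is not None:
        (out / "resolved_config.json").write_text(json.dumps(config, indent=2, sort_keys=True))
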