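"""CSV/JSON artifact writers and the scenario comparison report."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import pandas as pd

from .engine import Trajectory
from .model import OutcomeSummary
from .scenarios import OutcomeComparison, compare

__all__ = [
    "write_trajectory_csv",
    "write_summary_csv",
    "read_summary_csv",
    "write_provenance",
    "comparison_table",
    "plot_comparison",
]


def write_trajectory_csv(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False)


def write_summary_csv(summary: OutcomeSummary, path) -> None:
    pd.DataFrame([summary.__dict__]).to_csv(path, index=False)


def read_summary_csv(path) -> OutcomeSummary:
    row = pd.read_csv(path).iloc[0]
    return OutcomeSummary(**{k: float(row[k]) for k in OutcomeSummary.__dataclass_fields__})


def write_provenance(path, *, seed: int, config_text: str, extra: dict | None = None) -> None:
    """Record enough to reproduce a run: seed, config hash, versions."""
    import mhsd

    doc = {
        "seed": seed,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "mhsd_version": mhsd.__version__,
        "python_version": platform.python_version(),
        **(extra or {}),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def comparison_table(
    baseline: OutcomeSummary, scenarios: dict[str, OutcomeSummary]
) -> pd.DataFrame:
    """Tidy per-scenario comparison, ordered by self-harm reduction (desc)."""
    rows = []
    for name, summary in scenarios.items():
        rows.append({"scenario": name, **compare(baseline, summary).as_dict()})
    df = pd.DataFrame(rows)
    return df.sort_values(
        "pct_reduction_self_harm", ascending=False, ignore_index=True
    )


def plot_comparison(table: pd.DataFrame, out_dir) -> list[Path]:
    """One bar chart per outcome metric; returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    metrics = {
        "pct_reduction_self_harm": "Self-harm hospitalizations reduced (%)",
        "pct_reduction_suicide": "Suicide deaths reduced (%)",
        "pct_reduction_ed": "Mental-health ED presentations reduced (%)",
        "pp_reduction_prevalence": "High-distress prevalence reduced (pp, 2030)",
    }
    for metric, label in metrics.items():
        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.barh(table["scenario"], table[metric], color="#3a6ea5")
        ax.set_xlabel(label)
        ax.invert_yaxis()
        fig.tight_layout()
        path = out_dir / f"{metric}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
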