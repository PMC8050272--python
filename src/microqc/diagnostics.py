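"""Loss-curve quality control and the consolidated training/QC report.

A model is judged to overfit when the validation loss rebounds from its
minimum (final value more than ``(1 + delta)`` times the minimum) while the
training loss keeps falling — the divergence pattern that signals memorisation
of the training data.  The report gathers every parameter and QC scalar of a
run into a deterministic markdown + JSON twin suitable for pasting into a
Methods section.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

__all__ = ["LossCurves", "OverfitConfig", "analyze_loss", "read_loss_csv", "build_report"]


@dataclass
class LossCurves:
    """Per-epoch training and validation loss."""

    epochs: np.ndarray
    train_loss: np.ndarray
    val_loss: np.ndarray

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=int)
        self.train_loss = np.asarray(self.train_loss, dtype=float)
        self.val_loss = np.asarray(self.val_loss, dtype=float)
        if not (len(self.epochs) == len(self.train_loss) == len(self.val_loss)):
            raise ValueError("epochs, train_loss and val_loss must have equal length")
        if len(self.epochs) < 2:
            raise ValueError("need at least two epochs")
        for name, arr in (("train_loss", self.train_loss), ("val_loss", self.val_loss)):
            bad = np.nonzero(~np.isfinite(arr))[0]
            if len(bad):
                raise ValueError(f"non-finite {name} at epoch {self.epochs[bad[0]]}")


@dataclass
class OverfitConfig:
    """Relative tolerance on the validation-loss rebound."""

    delta: float = 0.05

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")


def read_loss_csv(path: str | Path) -> LossCurves:
    """Read a loss log CSV with columns epoch, train_loss, val_loss
    (``loss``/``val_loss`` Keras spellings accepted)."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    epoch = df[cols["epoch"]] if "epoch" in cols else pd.Series(np.arange(1, len(df) + 1))
    train = cols.get("train_loss") or cols.get("training loss") or cols.get("loss")
    val = cols.get("val_loss") or cols.get("validation loss")
    if train is None or val is None:
        raise ValueError(f"{path}: need train and validation loss columns, found {list(df.columns)}")
    return LossCurves(epoch.to_numpy(), df[train].to_numpy(), df[val].to_numpy())


def analyze_loss(curves: LossCurves, cfg: OverfitConfig | None = None) -> dict:
    """Overfitting verdict and best-checkpoint recommendation.

    Overfit means the final validation loss exceeds ``(1 + delta)`` times its
    minimum while the final training loss is at or below its value at the
    validation-minimum epoch.  The verdict is scale-invariant by construction.
    """
    cfg = cfg or OverfitConfig()
    k_min = int(np.argmin(curves.val_loss))
    min_val = float(curves.val_loss[k_min])
    final_val = float(curves.val_loss[-1])
    rebound = final_val / min_val if min_val > 0 else np.inf
    overfit = bool(
        final_val > (1 + cfg.delta) * min_val
        and curves.train_loss[-1] <= curves.train_loss[k_min]
    )
    return {
        "overfit": overfit,
        "best_epoch": int(curves.epochs[k_min]),
        "min_val_loss": min_val,
        "final_val_loss": final_val,
        "val_loss_rebound": float(rebound),
        "delta": cfg.delta,
    }


def build_report(
    run_config: dict,
    qc_results: dict | None = None,
    out_dir: str | Path | None = None,
    timestamp: str | None = None,
) -> tuple[str, dict]:
    """Build the consolidated training/QC report (markdown text, JSON twin).

    Everything except the single timestamp line is deterministic; passing
    ``timestamp`` explicitly makes the whole report reproducible.  When
    ``out_dir`` is given, ``report.md`` and ``report.json`` are written there.
    """
    qc_results = qc_results or {}
    if timestamp is None:
        timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")
    doc = {
        "toolkit": "microqc",
        "version": __version__,
        "timestamp": timestamp,
        "parameters": _jsonable(run_config),
        "qc": _jsonable(qc_results),
    }
    lines = [
        "# Training and quality-control report",
        "",
        f"Generated by microqc {__version__} at {timestamp}.",
        "",
        "## Parameters",
        "",
    ]
    lines += _kv_lines(doc["parameters"])
    if doc["qc"]:
        lines += ["", "## Quality control", ""]
        lines += _kv_lines(doc["qc"])
    lines.append("")
    markdown = "\n".join(lines)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.md").write_text(markdown)
        (out_dir / "report.json").write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return markdown, doc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return repr(obj)


def _kv_lines(mapping: dict, indent: int = 0) -> list[str]:
    lines = []
    for key, value in mapping.items():
        pad = "  " * indent
        if isinstance(value, dict):
            lines.append(f"{pad}- **{key}**:")
            lines += _kv_lines(value, indent + 1)
        else:
            lines.append(f"{pad}- **{key}**: {value}")
    return lines
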