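"""Configuration-driven end-to-end sensitivity runs.

``run_full`` executes the whole analysis from one :class:`RunConfig`:
simulate a cohort per mattress regime, sweep the spatial x temporal
configuration grid, score postural-event discrimination (AUC per
parameter per cell) and posture classification (accuracy per spatial
resolution), and write ``auc_grid.csv``, ``accuracy.csv`` and a
``run_manifest.json`` carrying every seed so any number in the outputs
can be regenerated.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import SplitPlan, accuracy_by_resolution
from .events import auc_grid
from .frames import PARAMETER_NAMES, ValidationError
from .nn import CNNConfig
from .resample import BLOCK_FACTORS, DECIMATION_FACTORS, enumerate_configurations
from .synth import SIM_POSTURES, SimulationScript, make_cohort

logger = logging.getLogger("ipmap")


@dataclass(frozen=True)
class RunConfig:
    """Everything a full sensitivity run depends on.

    Round-trips through YAML (:meth:`to_yaml` / :meth:`from_yaml`).  The
    cohort sizes of the motivating studies (20 and 27 subjects) are
    presets a config may opt into; the default is desk-scale.
    """

    n_subjects: int = 10
    regimes: tuple[str, ...] = ("foam", "air")
    seed: int = 0
    segments: tuple[tuple[str, float], ...] = (
        ("supine", 60.0),
        ("high_sitting", 60.0),
        ("supine", 60.0),
        ("lateral_right", 60.0),
    )
    transition_duration: float = 5.0
    noise_sd: float = 2.0
    blocks: tuple[int, ...] = BLOCK_FACTORS
    decimations: tuple[int, ...] = DECIMATION_FACTORS
    roc_tolerance: float | None = None
    classifier: CNNConfig = field(default_factory=CNNConfig)
    out_dir: str = "ipmap_run"

    def __post_init__(self) -> None:
        for regime in self.regimes:
            if regime not in ("foam", "air"):
                raise ValidationError(f"unknown regime {regime!r}")
        for posture, dur in self.segments:
            if posture not in SIM_POSTURES:
                raise ValidationError(f"unknown posture {posture!r} in script")
            if dur <= 0:
                raise ValidationError("segment durations must be positive")
        object.__setattr__(self, "regimes", tuple(self.regimes))
        object.__setattr__(
            self, "segments", tuple((p, float(d)) for p, d in self.segments)
        )
        object.__setattr__(self, "blocks", tuple(int(k) for k in self.blocks))
        object.__setattr__(self, "decimations", tuple(int(n) for n in self.decimations))

    def script(self) -> SimulationScript:
        return SimulationScript(
            segments=self.segments, transition_duration=self.transition_duration
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["segments"] = [list(s) for s in self.segments]
        payload["regimes"] = list(self.regimes)
        payload["blocks"] = list(self.blocks)
        payload["decimations"] = list(self.decimations)
        payload["classifier"] = asdict(self.classifier)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if "classifier" in payload:
            payload["classifier"] = CNNConfig(**payload["classifier"])
        if "segments" in payload:
            payload["segments"] = tuple((p, float(d)) for p, d in payload["segments"])
        for key in ("regimes", "blocks", "decimations"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return RunConfig(**payload)


@dataclass(frozen=True)
class SensitivityGrid:
    """The two output tables of a full run."""

    auc: pd.DataFrame  # regime, parameter, block, n_sensors, frequency, auc, ...
    accuracy: pd.DataFrame  # regime, block, n_sensors, accuracy


def run_full(config: RunConfig) -> SensitivityGrid:
    """Simulate -> down-sample grid -> extract -> ROC + classify.

    Writes ``auc_grid.csv``, ``accuracy.csv`` and ``run_manifest.json``
    into ``config.out_dir``; identical configs produce byte-identical
    CSVs.  Errors surface with the stage and configuration cell attached.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    script = config.script()

    auc_tables = []
    acc_tables = []
    cohort_seeds: dict[str, int] = {}
    for idx, regime in enumerate(config.regimes):
        cohort_seed = config.seed + 1000 * idx
        cohort_seeds[regime] = cohort_seed
        logger.info("simulate: regime=%s n_subjects=%d seed=%d",
                    regime, config.n_subjects, cohort_seed)
        cohort = make_cohort(
            config.n_subjects,
            regime=regime,
            seed=cohort_seed,
            script=script,
            noise_sd=config.noise_sd,
        )
        rows, cols = cohort[0].shape
        configs = enumerate_configurations(
            rows, cols, cohort[0].pitch, cohort[0].frequency,
            blocks=config.blocks, decimations=config.decimations,
        )
        logger.info("roc: regime=%s %d configurations", regime, len(configs))
        try:
            auc_tables.append(auc_grid(cohort, configs, tolerance=config.roc_tolerance))
        except Exception as exc:  # surface the stage and cell
            raise RuntimeError(f"stage=roc regime={regime}: {exc}") from exc
        logger.info("classify: regime=%s blocks=%s", regime, config.blocks)
        try:
            acc_tables.append(
                accuracy_by_resolution(
                    cohort,
                    ks=config.blocks,
                    split=SplitPlan(seed=config.seed),
                    arch=config.classifier,
                    seed=config.seed,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"stage=classify regime={regime}: {exc}") from exc

    grid = SensitivityGrid(
        auc=pd.concat(auc_tables, ignore_index=True),
        accuracy=pd.concat(acc_tables, ignore_index=True),
    )
    grid.auc.to_csv(out_dir / "auc_grid.csv", index=False, lineterminator="\n")
    grid.accuracy.to_csv(out_dir / "accuracy.csv", index=False, lineterminator="\n")
    manifest = {
        "config": json.loads(json.dumps(_config_payload(config))),
        "cohort_seeds": cohort_seeds,
        "package_version": __version__,
        "timestamp_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return grid


def _config_payload(config: RunConfig) -> dict:
    payload = asdict(config)
    payload["segments"] = [list(s) for s in config.segments]
    return payload


def report(grid: SensitivityGrid, out: str | Path) -> list[Path]:
    """Render the AUC trends and the accuracy table.

    One PNG per (parameter, regime): AUC versus sampling frequency, one
    line per spatial resolution.  Also writes ``accuracy_table.csv``.
    Returns the paths written.  A regime missing from the grid is skipped
    with a warning rather than an error.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if grid.auc.empty:
        raise ValidationError("cannot report an empty grid")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    regimes = sorted(grid.auc["regime"].unique())
    for expected in ("foam", "air"):
        if expected not in regimes:
            logger.warning("report: regime %s absent from grid, skipping", expected)
    for regime in regimes:
        sub_regime = grid.auc[grid.auc["regime"] == regime]
        for parameter in PARAMETER_NAMES:
            sub = sub_regime[sub_regime["parameter"] == parameter]
            if sub.empty:
                continue
            fig, ax = plt.subplots(figsize=(5, 3.5))
            for n_sensors, cell in sub.groupby("n_sensors"):
                cell = cell.sort_values("frequency_hz")
                ax.plot(
                    cell["frequency_hz"], cell["auc"], marker="o",
                    label=f"{n_sensors} sensors",
                )
            ax.set_xlabel("sampling frequency [Hz]")
            ax.set_ylabel("AUC")
            ax.set_ylim(0.0, 1.05)
            ax.set_title(f"{parameter} ({regime})")
            ax.legend(fontsize=7)
            fig.tight_layout()
            path = out / f"auc_{parameter}_{regime}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)

    acc_path = out / "accuracy_table.csv"
    grid.accuracy.to_csv(acc_path, index=False, lineterminator="\n")
    written.append(acc_path)
    return written
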