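"""End-to-end synthetic experiments: generation, scoring, statistics.

Two canned designs mirror the bioassay layouts the package analyses:

* ``run_dose_sweep`` — one extract, a log-spaced dose grid plus untreated
  control, Duncan lettering against the control, effect-onset and
  saturation detection.
* ``run_synthetic_experiment`` — the 12-condition alkaloid grid
  (3 tissues x 2 sites x 2 doses) with per-condition mortality simulation
  and the mortality-on-integrity regression.

All randomness derives from the one seed in the configuration: condition
``k`` of a grid generates its images with seeds ``seed + 1000*(k+1) + i``
and simulates mortality with seed ``seed + 500000 + k``, keeping every
stage reproducible and every image distinct.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import (
    AQUEOUS_DOSE_GRID,
    Condition,
    PipelineConfig,
    alkaloid_condition_grid,
    default_config,
)
from .groups import (
    DoseResponseTable,
    TreatmentGroup,
    dose_response,
    duncan_mrt,
    heatmap_summary,
    summarize_group,
)
from .io import scores_to_frame, write_batch
from .mortality import RegressionResult, mortality_fraction, regress_mortality_on_integrity
from .scoring import score_cell
from .synthetic import disintegration_from_dose, generate_batch, simulate_mortality

__all__ = [
    "ExperimentReport",
    "score_condition",
    "run_dose_sweep",
    "run_synthetic_experiment",
]

_CONDITION_SEED_STRIDE = 1000
_MORTALITY_SEED_OFFSET = 500000


@dataclass
class ExperimentReport:
    """All tables produced by one synthetic end-to-end run."""

    scores: pd.DataFrame
    summary: pd.DataFrame
    mortality: pd.DataFrame
    heatmaps: pd.DataFrame | None
    regression: RegressionResult | None
    run_log: dict

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        header = (f"# seed={self.run_log['seed']} "
                  f"score_signal={self.run_log['score_signal']} "
                  f"version={self.run_log['version']}\n")
        tables = [("scores.csv", self.scores), ("summary.csv", self.summary),
                  ("mortality.csv", self.mortality)]
        if self.heatmaps is not None:
            tables.append(("heatmap.csv", self.heatmaps))
        for name, frame in tables:
            with open(out_dir / name, "w") as fh:
                fh.write(header)
                frame.to_csv(fh, index=False)
        if self.regression is not None:
            payload = {"slope": self.regression.slope,
                       "intercept": self.regression.intercept,
                       "r_squared": self.regression.r_squared,
                       "n_points": self.regression.n_points,
                       **self.run_log}
            (out_dir / "regression.json").write_text(json.dumps(payload, indent=2))
        (out_dir / "run_log.json").write_text(json.dumps(self.run_log, indent=2))


def _run_log(config: PipelineConfig) -> dict:
    return {
        "seed": config.seed,
        "score_signal": config.protocol.score_signal,
        "alpha": config.alpha,
        "version": __version__,
    }


def score_condition(config: PipelineConfig, condition: Condition,
                    condition_index: int, n_cells: int | None = None,
                    out_dir: str | Path | None = None) -> tuple[TreatmentGroup, pd.DataFrame]:
    """Generate and score the cells of one condition.

    Returns the TreatmentGroup of per-cell scores and the score table.
    Writes TIFFs plus manifest when ``out_dir`` is given.
    """
    n_cells = n_cells or config.n_cells_per_condition
    seed = config.seed + _CONDITION_SEED_STRIDE * (condition_index + 1)
    params = config.synthetic.replace(disintegration=condition.disintegration)
    meta = {"tissue": condition.tissue, "site": condition.site,
            "fraction": condition.fraction, "dose": condition.dose,
            "d": condition.disintegration, "seed": seed}
    images = generate_batch(params, n_cells, seed, metadata=meta,
                            id_prefix=condition.label)
    if out_dir is not None:
        write_batch(images, Path(out_dir) / condition.label)
    scores = [score_cell(img, config.protocol) for img in images]
    group = TreatmentGroup(scores=[s.value for s in scores],
                           tissue=condition.tissue, site=condition.site,
                           fraction=condition.fraction, dose=condition.dose)
    table = scores_to_frame(scores, [meta] * len(scores))
    return group, table


def run_dose_sweep(config: PipelineConfig | None = None,
                   doses: tuple[float, ...] = AQUEOUS_DOSE_GRID,
                   n_cells: int | None = None,
                   verbose: bool = False) -> tuple[DoseResponseTable, pd.DataFrame]:
    """Dose sweep of one extract against an untreated control.

    Disintegration follows the config's Hill dose map; dose 0 is the
    control.  Returns the dose-response table (Duncan letters, effect
    onset, saturation) and the per-cell score table.
    """
    config = config or default_config()
    conditions = [Condition(tissue="bark", site="Sanankoroba",
                            fraction="control" if dose == 0 else "aqueous",
                            dose=dose,
                            disintegration=disintegration_from_dose(dose, config.dose_map))
                  for dose in (0.0, *doses)]
    groups, tables = [], []
    for k, cond in enumerate(conditions):
        group, table = score_condition(config, cond, k, n_cells=n_cells)
        groups.append(group)
        tables.append(table)
        if verbose:
            print(f"dose {cond.dose:g}: d={cond.disintegration:.3f} "
                  f"mean score {group.scores.mean():.1f}", file=sys.stderr)
    table = dose_response(groups[1:], control=groups[0], alpha=config.alpha)
    return table, pd.concat(tables, ignore_index=True)


def run_synthetic_experiment(config: PipelineConfig | None = None,
                             conditions: list[Condition] | None = None,
                             out_dir: str | Path | None = None,
                             write_images: bool = False,
                             verbose: bool = False) -> ExperimentReport:
    """The full synthetic chain: grid -> images -> scores -> statistics.

    Scores every condition of the grid (default: the 12-condition alkaloid
    grid), attaches Duncan letters, builds the tissue x site summary,
    simulates the Evans-blue mortality assay from each condition's mean
    score and fits the mortality-on-integrity regression.
    """
    config = config or default_config()
    conditions = conditions if conditions is not None else alkaloid_condition_grid()
    if not conditions:
        raise ValueError("no conditions in the experiment grid")

    image_dir = Path(out_dir) / "images" if (out_dir and write_images) else None
    groups, tables = [], []
    for k, cond in enumerate(conditions):
        try:
            group, table = score_condition(config, cond, k, out_dir=image_dir)
        except Exception as exc:
            raise RuntimeError(
                f"scoring stage failed for condition {cond.label}: {exc}") from exc
        groups.append(group)
        tables.append(table)
        if verbose:
            print(f"{cond.label}: d={cond.disintegration:.3f} "
                  f"mean score {group.scores.mean():.1f}", file=sys.stderr)
    scores = pd.concat(tables, ignore_index=True)

    letters = duncan_mrt(groups, alpha=config.alpha) if len(groups) > 1 else [""]
    rows = []
    for cond, group, letter in zip(conditions, groups, letters):
        s = summarize_group(group) if group.n >= 2 else None
        rows.append({
            "tissue": cond.tissue, "site": cond.site,
            "fraction": cond.fraction, "dose": cond.dose,
            "d": cond.disintegration,
            "mean": s.mean if s else float(group.scores.mean()),
            "se": s.se if s else np.nan,
            "n": group.n,
            "letter": letter if len(groups) > 1 else "",
        })
    summary = pd.DataFrame(rows)

    mort_rows, pairs = [], []
    for k, (cond, group) in enumerate(zip(conditions, groups)):
        try:
            records = simulate_mortality(
                float(group.scores.mean()), config.coupling,
                seed=config.seed + _MORTALITY_SEED_OFFSET + k,
                condition=(cond.tissue, cond.site, cond.fraction, cond.dose))
        except Exception as exc:
            raise RuntimeError(
                f"mortality stage failed for condition {cond.label}: {exc}") from exc
        mean_pct, se_pct = mortality_fraction(records)
        pairs.append((float(group.scores.mean()), mean_pct))
        for r in records:
            mort_rows.append({
                "tissue": cond.tissue, "site": cond.site,
                "fraction": cond.fraction, "dose": cond.dose,
                "replicate": r.replicate, "dead": r.dead, "total": r.total,
                "mortality_pct": 100.0 * r.dead / r.total,
            })
    mortality = pd.DataFrame(mort_rows)

    # per-dose tissue x site heat maps where the grid provides full cells
    heat_frames = []
    for dose in sorted({c.dose for c in conditions}):
        at_dose = [g for c, g in zip(conditions, groups) if c.dose == dose]
        cells = {(g.tissue, g.site) for g in at_dose}
        if len(cells) == len(at_dose) and len(at_dose) > 1:
            hm = heatmap_summary(at_dose).table.reset_index()
            hm.insert(0, "dose", dose)
            heat_frames.append(hm)
    heatmaps = pd.concat(heat_frames, ignore_index=True) if heat_frames else None

    regression = regress_mortality_on_integrity(pairs) if len(pairs) >= 3 else None

    report = ExperimentReport(scores=scores, summary=summary,
                              mortality=mortality, heatmaps=heatmaps,
                              regression=regression,
                              run_log=_run_log(config))
    if out_dir is not None:
        report.write(out_dir)
    return report
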