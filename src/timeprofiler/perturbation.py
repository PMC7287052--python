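"""Cell-line perturbation analysis: baseline metabolic state and paired
control-vs-treated panel shifts.

The experimental design emulated here is an L1000-style inhibitor study:
each cell line has DMSO control replicates and drug-treated replicates over
a shared gene set. Because replicate counts differ between arms, the pairing
unit for the treatment test is the *gene*: per gene, replicate means are
formed under each condition and the paired two-sided t-test runs across the
panel's (treated - control) differences.

Baseline characterization z-scores the control replicate means across cell
lines (per gene) and compares each line's panel-gene values against the
pooled other lines by Welch's t-test.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, zscore
from .genes import canonical_symbol

__all__ = [
    "load_perturbation",
    "write_perturbation",
    "validate_experiment",
    "baseline_panel_level",
    "treatment_shift",
    "PanelShiftResult",
    "panel_extension",
]

CONDITIONS = ("control", "treated")
_COLUMNS = ["cell_line", "condition", "replicate", "gene", "value"]


def load_perturbation(path: str | Path) -> pd.DataFrame:
    """Read a long-format experiment table (cell_line, condition, replicate,
    gene, value)."""
    df = pd.read_csv(path, sep="\t", dtype={"replicate": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    validate_experiment(df)
    return df[_COLUMNS]


def write_perturbation(df: pd.DataFrame, path: str | Path) -> None:
    df[_COLUMNS].to_csv(path, sep="\t", index=False)


def validate_experiment(df: pd.DataFrame) -> None:
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}")
    reps = df.groupby(["cell_line", "condition"])["replicate"].nunique()
    if (reps < 2).any():
        few = reps[reps < 2]
        raise ValueError(f"< 2 replicates for {list(few.index)}")


def _replicate_means(df: pd.DataFrame, cell_line: str, condition: str) -> pd.Series:
    sub = df[(df["cell_line"] == cell_line) & (df["condition"] == condition)]
    if sub.empty:
        raise ValueError(f"no {condition!r} data for cell line {cell_line!r}")
    wide = sub.pivot_table(index="gene", columns="replicate", values="value")
    return wide.mean(axis=1)


def baseline_panel_level(
    df: pd.DataFrame,
    panels: Mapping[str, Sequence[str]],
    *,
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Baseline (control) metabolic level of each cell line, per panel.

    Control replicate means are z-scored per gene across cell lines; a line's
    panel score is the mean z of the panel genes, tested against the pooled
    panel-gene z-values of all other lines (Welch two-sided t).

    Returns a DataFrame with cell_line, panel, n_genes, mean_z, t, p.
    """
    lines = sorted(df["cell_line"].unique())
    if len(lines) < 2:
        raise ValueError("baseline comparison needs >= 2 cell lines")
    means = pd.DataFrame(
        {line: _replicate_means(df, line, "control") for line in lines}
    ).dropna()
    z = zscore(ExpressionMatrix(means)).data

    rows = []
    for panel_name, genes in panels.items():
        canon = {canonical_symbol(g, aliases) for g in genes}
        present = [g for g in z.index if canonical_symbol(g, aliases) in canon]
        if len(present) < 2:
            warnings.warn(
                f"panel {panel_name!r}: < 2 genes measured; skipped", stacklevel=2
            )
            continue
        block = z.loc[present]
        for line in lines:
            own = block[line].to_numpy(dtype=float)
            others = block.drop(columns=line).to_numpy(dtype=float).ravel()
            if np.allclose(own, own.mean()) and np.allclose(others, own.mean()):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(own, others, equal_var=False)
            rows.append(
                {
                    "cell_line": line,
                    "panel": panel_name,
                    "n_genes": len(present),
                    "mean_z": float(own.mean()),
                    "t_statistic": float(t),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PanelShiftResult:
    """Paired control->treated shift of a panel in one cell line."""

    cell_line: str
    panel: str
    n_genes: int
    mean_control: float
    mean_treated: float
    mean_diff: float
    t_statistic: float
    p_value: float
    direction: str  # "down" | "up" | "none"


def treatment_shift(
    df: pd.DataFrame,
    cell_line: str,
    panel_genes: Sequence[str],
    panel_name: str = "panel",
    *,
    aliases: Mapping[str, str] | None = None,
) -> PanelShiftResult:
    """Paired t-test of a panel's expression before vs after treatment.

    Per panel gene: replicate-mean under control and under treatment; the
    test is the paired two-sided t across genes on (treated - control),
    equivalently a one-sample t of the difference vector against 0.
    """
    ctrl = _replicate_means(df, cell_line, "control")
    trt = _replicate_means(df, cell_line, "treated")
    canon = {canonical_symbol(g, aliases) for g in panel_genes}
    common = [
        g
        for g in ctrl.index.intersection(trt.index)
        if canonical_symbol(g, aliases) in canon
    ]
    if len(common) < 2:
        raise ValueError(
            f"panel {panel_name!r}: only {len(common)} gene(s) measured in both "
            f"conditions of {cell_line!r}"
        )
    c = ctrl.loc[common].to_numpy(dtype=float)
    t_arr = trt.loc[common].to_numpy(dtype=float)
    diff = t_arr - c
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if diff.mean() == 0.0:
            tstat, p = 0.0, 1.0
        else:  # constant nonzero shift: infinitely strong evidence
            tstat, p = float(np.sign(diff.mean()) * np.inf), 0.0
    else:
        tstat, p = stats.ttest_rel(t_arr, c)
    mean_diff = float(diff.mean())
    if p < 1.0 and mean_diff != 0.0:
        direction = "down" if mean_diff < 0 else "up"
    else:
        direction = "none"
    return PanelShiftResult(
        cell_line=cell_line,
        panel=panel_name,
        n_genes=len(common),
        mean_control=float(c.mean()),
        mean_treated=float(t_arr.mean()),
        mean_diff=mean_diff,
        t_statistic=float(tstat),
        p_value=float(p),
        direction=direction,
    )


def panel_extension(
    base: Sequence[str],
    extra: Sequence[str],
    *,
    aliases: Mapping[str, str] | None = None,
) -> list[str]:
    """Merge a base panel with an extension list, deduplicating by alias.

    Order is base first, then novel extension genes; duplicates (after alias
    resolution) are merged with a warning. Returns the concatenated list.
    """
    seen: dict[str, str] = {}
    merged: list[str] = []
    overlaps: list[str] = []
    for g in list(base) + list(extra):
        key = canonical_symbol(g, aliases)
        if key in seen:
            overlaps.append(g)
            continue
        seen[key] = g
        merged.append(g)
    if overlaps:
        warnings.warn(
            f"{len(overlaps)} duplicate gene(s) merged during panel extension: "
            f"{overlaps[:5]}...",
            stacklevel=2,
        )
    return merged
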