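"""Glycolysis vs OXPHOS metabolic phenotyping.

A tumor's metabolic lean is summarized by *upregulation frequencies*: within
a sample stratum (e.g. regulator-high vs regulator-low expressers), the
fraction of samples with z > 0 is computed for each gene of the 24-gene
glycolysis panel and the 31-gene OXPHOS panel. Per-gene differences between
strata are tested by Fisher's exact test; panel-level differences by a
Welch unpaired two-tailed t-test over the per-gene fraction vectors; and the
relative phenotype normalizes the two panel means to shares summing to 1
(a Warburg-vs-respiration balance readout).
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .core import ZExpressionMatrix
from .enrichment import fisher_exact_2x2
from .genes import resolve_symbol

__all__ = [
    "MetabolicPanels",
    "default_panels",
    "load_panels",
    "UpregulationProfile",
    "upregulation_profile",
    "compare_gene_upregulation",
    "compare_panel_means",
    "relative_phenotype",
    "export_wordcloud_weights",
]


@dataclass(frozen=True)
class MetabolicPanels:
    """The two metabolic gene panels (disjoint symbol lists)."""

    glycolysis: tuple[str, ...]
    oxphos: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.glycolysis) & set(self.oxphos):
            raise ValueError("glycolysis and oxphos panels overlap")

    def as_dict(self) -> dict[str, tuple[str, ...]]:
        return {"glycolysis": self.glycolysis, "oxphos": self.oxphos}


def load_panels(path: str | Path) -> MetabolicPanels:
    """Load panels from a user YAML file (keys ``glycolysis``, ``oxphos``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return MetabolicPanels(tuple(raw["glycolysis"]), tuple(raw["oxphos"]))


def default_panels() -> MetabolicPanels:
    """The shipped 24-gene glycolysis / 31-gene OXPHOS panels."""
    raw = yaml.safe_load(
        resources.files("timeprofiler.data")
        .joinpath("metabolic_panels.yaml")
        .read_text()
    )
    return MetabolicPanels(tuple(raw["glycolysis"]), tuple(raw["oxphos"]))


@dataclass
class UpregulationProfile:
    """Per gene x stratum upregulated fractions (and the counts behind them).

    ``table`` columns: gene, panel, frac_high, frac_low, n_up_high, n_high,
    n_up_low, n_low. ``dropped`` lists panel genes absent from the matrix.
    """

    table: pd.DataFrame
    dropped: tuple[str, ...] = ()


def upregulation_profile(
    z: ZExpressionMatrix,
    panels: MetabolicPanels,
    strata: pd.Series,
    *,
    aliases: Mapping[str, str] | None = None,
    threshold: float = 0.0,
) -> UpregulationProfile:
    """Fraction of samples with z > threshold per panel gene, per stratum.

    ``strata`` is a per-sample series with levels ``high`` and ``low`` (other
    levels, e.g. ``mid``, are ignored). "Upregulated" is strict: a z-score of
    exactly 0 — in particular every degenerate, zero-variance gene — does not
    count. Panel genes missing from the matrix are dropped with a warning.
    """
    groups = {}
    for level in ("high", "low"):
        ids = strata.index[strata == level].intersection(z.data.columns)
        if len(ids) == 0:
            raise ValueError(f"stratum {level!r} is empty")
        groups[level] = ids

    rows = []
    dropped: list[str] = []
    for panel_name, genes in panels.as_dict().items():
        for gene in genes:
            try:
                resolved = resolve_symbol(gene, z.data.index, aliases)
            except KeyError:
                dropped.append(gene)
                continue
            row = z.data.loc[resolved]
            rec: dict = {"gene": gene, "panel": panel_name}
            for level, ids in groups.items():
                vals = row.loc[ids]
                n_up = int((vals > threshold).sum())
                rec[f"frac_{level}"] = n_up / len(ids)
                rec[f"n_up_{level}"] = n_up
                rec[f"n_{level}"] = len(ids)
            rows.append(rec)
    if dropped:
        warnings.warn(
            f"panel genes absent from matrix, dropped: {dropped}", stacklevel=2
        )
    return UpregulationProfile(pd.DataFrame(rows), tuple(dropped))


def compare_gene_upregulation(
    profile: UpregulationProfile, gene: str
) -> tuple[np.ndarray, float]:
    """Fisher 2x2 of one gene's up/not-up counts between high and low strata."""
    row = profile.table.loc[profile.table["gene"] == gene]
    if row.empty:
        raise KeyError(f"gene {gene!r} not in profile")
    r = row.iloc[0]
    table = np.array(
        [
            [r["n_up_high"], r["n_high"] - r["n_up_high"]],
            [r["n_up_low"], r["n_low"] - r["n_up_low"]],
        ],
        dtype=np.int64,
    )
    _, p = fisher_exact_2x2(table)
    return table, p


@dataclass
class PanelMeanComparison:
    panel: str
    mean_high: float
    mean_low: float
    t_statistic: float
    p_value: float
    n_genes: int


def compare_panel_means(
    profile: UpregulationProfile, panel: str, *, equal_var: bool = False
) -> PanelMeanComparison:
    """Unpaired two-tailed t-test between strata on a panel's fraction vectors.

    The observations are the per-gene upregulation fractions (one value per
    gene per stratum), treated as unpaired samples. Welch (unequal-variance)
    by default; ``equal_var=True`` gives the Student variant.
    """
    sub = profile.table.loc[profile.table["panel"] == panel]
    if len(sub) < 2:
        raise ValueError(f"panel {panel!r} has < 2 genes with defined fractions")
    high = sub["frac_high"].to_numpy(dtype=float)
    low = sub["frac_low"].to_numpy(dtype=float)
    if np.allclose(high, high[0]) and np.allclose(low, low[0]) and np.isclose(
        high[0], low[0]
    ):
        t, p = 0.0, 1.0  # identical constant vectors: no evidence either way
    else:
        t, p = stats.ttest_ind(high, low, equal_var=equal_var)
    return PanelMeanComparison(
        panel, float(high.mean()), float(low.mean()), float(t), float(p), len(sub)
    )


def relative_phenotype(profile: UpregulationProfile) -> pd.DataFrame:
    """Glycolysis/OXPHOS shares per stratum (mean fractions normalized to 1)."""
    rows = []
    for level in ("high", "low"):
        means = {}
        for panel in ("glycolysis", "oxphos"):
            sub = profile.table.loc[profile.table["panel"] == panel]
            if sub.empty:
                raise ValueError(f"panel {panel!r} not scored in profile")
            means[panel] = float(sub[f"frac_{level}"].mean())
        total = means["glycolysis"] + means["oxphos"]
        if total == 0:
            raise ValueError(f"both panel means are zero in stratum {level!r}")
        rows.append(
            {
                "stratum": level,
                "glycolysis_share": means["glycolysis"] / total,
                "oxphos_share": means["oxphos"] / total,
            }
        )
    return pd.DataFrame(rows)


def export_wordcloud_weights(
    profile: UpregulationProfile,
    stratum: str,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Frequency-weighted gene list for word-cloud rendering (export only).

    One row per profiled gene with its upregulation fraction as the weight;
    stable gene order, byte-identical output for fixed input.
    """
    col = f"frac_{stratum}"
    if col not in profile.table.columns:
        raise KeyError(f"stratum {stratum!r} not in profile")
    out = profile.table[["gene", "panel", col]].rename(columns={col: "weight"})
    if path is not None:
        out.to_csv(path, sep="\t", index=False)
    return out
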