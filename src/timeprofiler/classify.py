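"""TIME subtype classification from directional gene panels.

A tumor immune microenvironment (TIME) subtype is called by a conjunctive
rule over immune-marker z-scores: a sample belongs to a subtype iff *every*
panel gene lies strictly on its required side of the threshold (default
z = 0, the cohort mean). Samples satisfying zero rules — or, for custom rule
sets, more than one — are left *unclassified*; with stringent conjunctive
rules that is the majority of a real cohort, which is the point: the three
called groups are clean prototypes of activated / suppressed / absent
immune microenvironments.

Also here: the two-gene cytolytic-activity call (simultaneous granzyme-B and
perforin up- or down-regulation) and single-gene expression stratification
(|z| >= kappa splits high / low / mid), both reused throughout the mutation
and metabolism analyses.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import ZExpressionMatrix
from .enrichment import fisher_exact_2x2
from .genes import resolve_symbol

__all__ = [
    "GenePanel",
    "SubtypeRuleSet",
    "default_ruleset",
    "panel_satisfied",
    "assign_subtypes",
    "call_cytact",
    "stratify_expression",
    "subtype_summary",
    "SummaryResult",
    "SUBTYPES",
]

SUBTYPES = ("activated", "suppressed", "absent")

Direction = str  # "up" | "down"


@dataclass(frozen=True)
class GenePanel:
    """A named set of (gene, required direction) pairs with a z threshold."""

    name: str
    entries: tuple[tuple[str, Direction], ...]
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"panel {self.name!r} has no entries")
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise ValueError(f"panel {self.name!r} has duplicate genes")
        for g, d in self.entries:
            if d not in ("up", "down"):
                raise ValueError(f"panel {self.name!r}: bad direction {d!r} for {g}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "threshold": self.threshold,
            "entries": [{"gene": g, "direction": d} for g, d in self.entries],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenePanel":
        return cls(
            name=d["name"],
            entries=tuple((e["gene"], e["direction"]) for e in d["entries"]),
            threshold=float(d.get("threshold", 0.0)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


@dataclass(frozen=True)
class SubtypeRuleSet:
    """Ordered panels for the activated / suppressed / absent subtypes.

    ``mode='all'`` (default) is the strict conjunction; ``mode='mean'`` calls
    a panel satisfied when the mean direction-signed z exceeds the threshold
    (a composite-score sensitivity analysis, not the primary rule).
    """

    activated: GenePanel
    suppressed: GenePanel
    absent: GenePanel
    mode: str = "all"

    def panels(self) -> dict[str, GenePanel]:
        return {
            "activated": self.activated,
            "suppressed": self.suppressed,
            "absent": self.absent,
        }


#: Immune markers with established diagnostic-pathology antibodies.
IMMUNE_MARKERS = (
    "PTPRC",   # CD45, pan-leukocyte
    "CD8A",    # cytotoxic T cells
    "FOXP3",   # regulatory T cells
    "CD79A",   # B cells
    "CD68",    # macrophages
    "GZMB",    # granzyme B
    "PRF1",    # perforin
    "S100A9",  # myeloid-derived suppressor cells
)

CYTOTOXIC_MARKERS = ("CD8A", "GZMB", "PRF1")


def default_ruleset(threshold: float = 0.0, *, mode: str = "all") -> SubtypeRuleSet:
    """The shipped (reconstructed) subtype rules.

    activated — cytotoxic T-cell response genes up (PTPRC, CD8A, GZMB, PRF1);
    suppressed — cytotoxic genes down with the macrophage marker CD68 and the
    MDSC marker S100A9 up; absent — every immune marker down. The panels are
    a reconstruction from the marker list and the published prose and are
    overridable via YAML/JSON.
    """
    activated = GenePanel(
        "activated",
        tuple((g, "up") for g in ("PTPRC", "CD8A", "GZMB", "PRF1")),
        threshold,
    )
    suppressed = GenePanel(
        "suppressed",
        tuple((g, "down") for g in CYTOTOXIC_MARKERS)
        + (("CD68", "up"), ("S100A9", "up")),
        threshold,
    )
    absent = GenePanel(
        "absent", tuple((g, "down") for g in IMMUNE_MARKERS), threshold
    )
    return SubtypeRuleSet(activated, suppressed, absent, mode=mode)


def _panel_matrix(
    z: ZExpressionMatrix, panel: GenePanel, aliases: Mapping[str, str] | None
) -> pd.DataFrame:
    rows = {}
    for gene, _ in panel.entries:
        resolved = resolve_symbol(gene, z.data.index, aliases)
        rows[gene] = z.data.loc[resolved]
    return pd.DataFrame(rows).T  # panel genes × samples


def _satisfied_all(
    z: ZExpressionMatrix, panel: GenePanel, aliases: Mapping[str, str] | None
) -> pd.Series:
    mat = _panel_matrix(z, panel, aliases)
    ok = pd.Series(True, index=z.data.columns)
    for gene, direction in panel.entries:
        row = mat.loc[gene]
        ok &= (row > panel.threshold) if direction == "up" else (row < panel.threshold)
    return ok


def _satisfied_mean(
    z: ZExpressionMatrix, panel: GenePanel, aliases: Mapping[str, str] | None
) -> pd.Series:
    mat = _panel_matrix(z, panel, aliases)
    signs = pd.Series(
        {g: (1.0 if d == "up" else -1.0) for g, d in panel.entries}
    )
    score = mat.mul(signs, axis=0).mean(axis=0)
    return score > panel.threshold


def panel_satisfied(
    z: ZExpressionMatrix,
    sample: str,
    panel: GenePanel,
    *,
    aliases: Mapping[str, str] | None = None,
    mode: str = "all",
) -> bool:
    """True iff the sample meets every directional requirement of the panel.

    Strict inequalities: a z-score exactly at the threshold satisfies neither
    direction (the cohort mean is deliberately unassignable).
    """
    if sample not in z.data.columns:
        raise KeyError(f"sample {sample!r} not in matrix")
    fn = _satisfied_all if mode == "all" else _satisfied_mean
    return bool(fn(z, panel, aliases)[sample])


def assign_subtypes(
    z: ZExpressionMatrix,
    rules: SubtypeRuleSet | None = None,
    *,
    aliases: Mapping[str, str] | None = None,
) -> pd.Series:
    """Label every sample activated / suppressed / absent / unclassified.

    A sample receives a subtype iff it satisfies *exactly one* of the three
    panels; zero or multiple satisfied panels yield ``unclassified``. (With
    the default rules two panels can never hold simultaneously — they demand
    opposite GZMB directions — but custom rule sets are not so constrained.)
    """
    rules = rules or default_ruleset()
    fn = _satisfied_all if rules.mode == "all" else _satisfied_mean
    sat = pd.DataFrame(
        {name: fn(z, panel, aliases) for name, panel in rules.panels().items()}
    )
    n_sat = sat.sum(axis=1)
    labels = pd.Series("unclassified", index=z.data.columns, name="subtype")
    exactly_one = n_sat == 1
    labels[exactly_one] = sat.loc[exactly_one].idxmax(axis=1)
    return labels


def call_cytact(
    z: ZExpressionMatrix,
    up_genes: Sequence[str] = ("GZMB", "PRF1"),
    threshold: float = 0.0,
    *,
    aliases: Mapping[str, str] | None = None,
) -> pd.Series:
    """Cytolytic-activity call: up / down / neither per sample.

    ``up`` requires *simultaneous* upregulation (all genes strictly above the
    threshold), ``down`` simultaneous downregulation; discordant pairs are
    ``neither``.
    """
    rows = [
        z.data.loc[resolve_symbol(g, z.data.index, aliases)] for g in up_genes
    ]
    mat = pd.concat(rows, axis=1)
    up = (mat > threshold).all(axis=1)
    down = (mat < threshold).all(axis=1)
    out = pd.Series("neither", index=z.data.columns, name="cytact")
    out[up] = "up"
    out[down] = "down"
    return out


def stratify_expression(
    z: ZExpressionMatrix,
    gene: str,
    kappa: float = 1.0,
    *,
    aliases: Mapping[str, str] | None = None,
) -> pd.Series:
    """Split samples on one gene: high (z >= +kappa), low (z <= -kappa), mid.

    Boundaries are inclusive so that ties at exactly +-kappa are deterministic.
    """
    row = z.data.loc[resolve_symbol(gene, z.data.index, aliases)]
    out = pd.Series("mid", index=z.data.columns, name=f"{gene}_stratum")
    out[row >= kappa] = "high"
    out[row <= -kappa] = "low"
    return out


@dataclass
class SummaryResult:
    """Per-subtype covariate breakdown (counts, integer percents, Fisher p)."""

    counts: pd.DataFrame
    pairwise_p: pd.DataFrame = field(default_factory=pd.DataFrame)


def subtype_summary(
    assignment: pd.Series,
    clinical: pd.DataFrame,
    covariates: Sequence[str] = ("hpv_status",),
) -> SummaryResult:
    """Tabulate covariates across subtypes, Table-1 style.

    For each covariate level: count and percent (rounded to integer percent)
    of each subtype carrying that level, plus pairwise Fisher exact p-values
    between subtypes on the level-vs-rest dichotomy.
    """
    counts_rows = []
    pairwise_rows = []
    groups = {
        s: assignment.index[assignment == s]
        for s in (*SUBTYPES, "unclassified")
    }
    for cov in covariates:
        if cov not in clinical.columns:
            warnings.warn(f"covariate {cov!r} missing from clinical table",
                          stacklevel=2)
            continue
        levels = sorted(set(clinical[cov].dropna().astype(str)))
        for level in levels:
            flag = clinical[cov].astype(str) == level
            per_subtype: dict[str, tuple[int, int]] = {}
            for subtype, ids in groups.items():
                ids = [i for i in ids if i in clinical.index]
                n = len(ids)
                if n == 0:
                    if subtype != "unclassified":
                        warnings.warn(
                            f"subtype {subtype!r} empty; no summary row",
                            stacklevel=2,
                        )
                    continue
                k = int(flag.loc[ids].sum())
                per_subtype[subtype] = (k, n)
                counts_rows.append(
                    {
                        "covariate": cov,
                        "level": level,
                        "subtype": subtype,
                        "n": k,
                        "total": n,
                        "percent": int(round(100.0 * k / n)),
                    }
                )
            named = [s for s in SUBTYPES if s in per_subtype]
            for i, a in enumerate(named):
                for b in named[i + 1 :]:
                    ka, na = per_subtype[a]
                    kb, nb = per_subtype[b]
                    _, p = fisher_exact_2x2([[ka, na - ka], [kb, nb - kb]])
                    pairwise_rows.append(
                        {
                            "covariate": cov,
                            "level": level,
                            "subtype_a": a,
                            "subtype_b": b,
                            "p": p,
                        }
                    )
    return SummaryResult(pd.DataFrame(counts_rows), pd.DataFrame(pairwise_rows))
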