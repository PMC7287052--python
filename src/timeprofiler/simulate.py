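"""Synthetic cohort and perturbation-experiment generators with planted truth.

Expression is generated directly on the z-scale — background genes are
standard normal per sample — because every classification rule downstream
operates on z-scores; simulating raw expression units would add nothing
testable. Planted structure:

* three TIME subtypes shift the eight immune-marker genes by +-``immune_shift``
  sd in the directions their rules require, while the *unclassified* majority
  is drawn by rejection sampling (immune values redrawn until no subtype rule
  holds on the raw scale), so the exclusion path is exercised by construction;
* one mutated gene is enriched in a target subtype (``mut_enriched_rate``
  there vs ``mut_base_rate`` elsewhere) on top of >= 20 neutral mutated genes;
* a regulator gene is coupled to the glycolysis program with correlation
  +rho and to the OXPHOS program with -rho, via
  ``gene = +-rho * regulator + sqrt(1 - rho^2) * noise``;
* survival is exponential with a per-subtype hazard, censored by an
  independent Uniform(0, 3/max-hazard) time (roughly 20-40 % censoring at the
  default hazards).

Default cohort composition mirrors a 530-patient cohort splitting
20 / 35 / 100 / 375 into activated / suppressed / absent / unclassified.
One integer seed drives a single ``numpy.random.default_rng`` stream, so a
fixed config is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import CYTOTOXIC_MARKERS, IMMUNE_MARKERS, default_ruleset
from .core import ExpressionMatrix, MutationTable, write_clinical, write_expression, write_mutations
from .genes import canonical_symbol
from .metabolism import default_panels

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "PerturbationSim",
    "generate_perturbation",
    "CELL_LINES",
]

_SUBTYPE_ORDER = ("activated", "suppressed", "absent", "unclassified")


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions.

    Proportions follow the 20/35/100/375-of-530 split; the planted mutated
    gene is enriched in the activated subtype (0.5 vs 0.05), the regulator is
    coupled to metabolism at rho = 0.8, and the activated subtype enjoys half
    the baseline hazard of the other groups.
    """

    n_samples: int = 530
    subtype_proportions: tuple[float, float, float, float] = (
        20 / 530,
        35 / 530,
        100 / 530,
        375 / 530,
    )
    immune_shift: float = 3.0
    n_background_genes: int = 100
    planted_mut_gene: str = "EP300"
    mut_target_subtype: str = "activated"
    mut_base_rate: float = 0.05
    mut_enriched_rate: float = 0.5
    n_neutral_mut_genes: int = 20
    regulator_gene: str = "EP300"
    metab_coupling: float = 0.8
    survival_hazards: dict = field(
        default_factory=lambda: {
            "activated": 5e-4,
            "suppressed": 1e-3,
            "absent": 1e-3,
            "unclassified": 1e-3,
        }
    )
    hpv_rates: dict = field(
        default_factory=lambda: {
            "activated": 0.45,
            "suppressed": 0.14,
            "absent": 0.06,
            "unclassified": 0.13,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.subtype_proportions, dtype=float)
        if p.size != 4 or (p < 0).any() or (p > 1).any():
            raise ValueError("subtype_proportions must be four values in [0,1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("subtype_proportions must sum to 1")
        for r in (self.mut_base_rate, self.mut_enriched_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("mutation rates must lie in [0,1]")
        if not abs(self.metab_coupling) < 1.0:
            raise ValueError("|metab_coupling| must be < 1")
        if self.mut_target_subtype not in _SUBTYPE_ORDER:
            raise ValueError(f"unknown target subtype {self.mut_target_subtype!r}")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    mutations: MutationTable
    clinical: pd.DataFrame
    truth: pd.DataFrame  # sample_id-indexed: subtype, planted_mutation
    config: CohortConfig


def _draw_unclassified_immune(
    rng: np.random.Generator, rules, thresholds: np.ndarray
) -> np.ndarray:
    """Immune-marker values violating every subtype rule.

    The violation is checked against each gene's *anticipated cohort mean*
    (``thresholds``) rather than raw zero: cohort-wide z-scoring recentres
    every gene on its mixture mean, so only violations relative to that mean
    survive standardization.
    """
    panels = rules.panels()
    idx = {g: i for i, g in enumerate(IMMUNE_MARKERS)}
    while True:
        vals = rng.standard_normal(len(IMMUNE_MARKERS))
        ok = False
        for panel in panels.values():
            sat = all(
                (vals[idx[g]] > thresholds[idx[g]])
                if d == "up"
                else (vals[idx[g]] < thresholds[idx[g]])
                for g, d in panel.entries
            )
            if sat:
                ok = True
                break
        if not ok:
            return vals


def generate_cohort(cfg: CohortConfig) -> SyntheticCohort:
    """Simulate expression + mutations + clinical data with known truth."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    samples = [f"S{i:04d}" for i in range(1, n + 1)]

    subtype = rng.choice(_SUBTYPE_ORDER, size=n, p=cfg.subtype_proportions)

    # --- immune markers -------------------------------------------------
    rules = default_ruleset()
    delta = cfg.immune_shift
    gidx = {g: i for i, g in enumerate(IMMUNE_MARKERS)}
    # Anticipated cohort mean per immune gene under the planted mixture
    # (unclassified samples contribute ~0). Cohort z-scoring recentres each
    # gene on this mean, so it is the raw-scale image of the z = 0 threshold.
    p_act, p_sup, p_abs, _ = cfg.subtype_proportions
    mix_mean = np.zeros(len(IMMUNE_MARKERS))
    for g, i in gidx.items():
        up_p = p_act + (p_sup if g in ("CD68", "S100A9") else 0.0)
        down_p = p_abs + (p_sup if g in CYTOTOXIC_MARKERS else 0.0)
        mix_mean[i] = delta * (up_p - down_p)

    immune = rng.standard_normal((len(IMMUNE_MARKERS), n))
    for j, s in enumerate(subtype):
        if s == "activated":
            immune[:, j] += delta
        elif s == "suppressed":
            for g in CYTOTOXIC_MARKERS:
                immune[gidx[g], j] -= delta
            immune[gidx["CD68"], j] += delta
            immune[gidx["S100A9"], j] += delta
        elif s == "absent":
            immune[:, j] -= delta
        else:
            immune[:, j] = _draw_unclassified_immune(rng, rules, mix_mean)
    # recentre so each gene's marginal cohort mean is ~0, matching the
    # z-scale contract for the generated matrix
    immune -= mix_mean[:, None]

    # --- regulator + metabolic programs ---------------------------------
    panels = default_panels()
    glyc = [canonical_symbol(g) for g in panels.glycolysis]
    oxph = [canonical_symbol(g) for g in panels.oxphos]
    rho = cfg.metab_coupling
    regulator = rng.standard_normal(n)
    noise_g = rng.standard_normal((len(glyc), n))
    noise_o = rng.standard_normal((len(oxph), n))
    glyc_expr = rho * regulator + np.sqrt(1 - rho**2) * noise_g
    oxph_expr = -rho * regulator + np.sqrt(1 - rho**2) * noise_o

    # --- background ------------------------------------------------------
    bg_genes = [f"BG{i:04d}" for i in range(1, cfg.n_background_genes + 1)]
    background = rng.standard_normal((len(bg_genes), n))

    gene_order = (
        list(IMMUNE_MARKERS) + [cfg.regulator_gene] + glyc + oxph + bg_genes
    )
    values = np.vstack([immune, regulator[None, :], glyc_expr, oxph_expr, background])
    expression = ExpressionMatrix(
        pd.DataFrame(values, index=gene_order, columns=samples)
    )

    # --- mutations --------------------------------------------------------
    planted_rate = np.where(
        subtype == cfg.mut_target_subtype, cfg.mut_enriched_rate, cfg.mut_base_rate
    )
    planted = rng.random(n) < planted_rate
    records: list[dict] = []

    def _add_records(gene: str, carrier_mask: np.ndarray) -> None:
        extra = rng.poisson(0.1, size=n)  # occasional multi-hit patients
        for j in np.nonzero(carrier_mask)[0]:
            for _ in range(1 + extra[j]):
                records.append(
                    {
                        "sample_id": samples[j],
                        "gene": gene,
                        "variant_class": "Missense_Mutation",
                    }
                )

    _add_records(cfg.planted_mut_gene, planted)
    neutral_genes = bg_genes[: cfg.n_neutral_mut_genes]
    for gene in neutral_genes:
        _add_records(gene, rng.random(n) < cfg.mut_base_rate)

    mutations = MutationTable(
        pd.DataFrame(records, columns=["sample_id", "gene", "variant_class"]),
        profiled_samples=frozenset(samples),
    )

    # --- clinical ---------------------------------------------------------
    hazards = np.array([cfg.survival_hazards[s] for s in subtype])
    lam_max = max(cfg.survival_hazards.values())
    event_os = rng.exponential(1.0 / hazards)
    cens_os = rng.uniform(0.0, 3.0 / lam_max, size=n)
    os_time = np.minimum(event_os, cens_os)
    os_event = (event_os <= cens_os).astype(int)
    event_dfs = rng.exponential(1.0 / (1.3 * hazards))
    cens_dfs = rng.uniform(0.0, 3.0 / lam_max, size=n)
    dfs_time = np.minimum(event_dfs, cens_dfs)
    dfs_event = (event_dfs <= cens_dfs).astype(int)

    hpv_rate = np.array([cfg.hpv_rates[s] for s in subtype])
    hpv = np.where(rng.random(n) < hpv_rate, "positive", "negative")
    site_p = {
        "activated": [0.55, 0.30, 0.15],
        "suppressed": [0.12, 0.58, 0.30],
        "absent": [0.08, 0.62, 0.30],
        "unclassified": [0.15, 0.60, 0.25],
    }
    sites = np.array(
        [
            rng.choice(["oropharynx", "oral_cavity", "larynx"], p=site_p[s])
            for s in subtype
        ]
    )
    stages = rng.choice(["I", "II", "III", "IV"], size=n, p=[0.05, 0.18, 0.21, 0.56])

    clinical = pd.DataFrame(
        {
            "hpv_status": hpv,
            "anatomical_site": sites,
            "stage": stages,
            "os_time": np.round(os_time, 2),
            "os_event": os_event,
            "dfs_time": np.round(dfs_time, 2),
            "dfs_event": dfs_event,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    truth = pd.DataFrame(
        {
            "subtype": subtype,
            "planted_mutation": planted,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return SyntheticCohort(expression, mutations, clinical, truth, cfg)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write expression/mutations/clinical + truth sidecar + config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "mutations": outdir / "mutations.maf",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "cohort_config.yaml",
    }
    write_expression(cohort.expression, paths["expression"])
    write_mutations(cohort.mutations, paths["mutations"])
    write_clinical(cohort.clinical, paths["clinical"])
    cohort.truth.to_csv(paths["truth"], sep="\t")
    cfg = dataclasses.asdict(cohort.config)
    cfg["subtype_proportions"] = [float(x) for x in cfg["subtype_proportions"]]
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=False))
    return paths


# ---------------------------------------------------------------------------
# perturbation experiments

#: the eight profiled cell lines of the emulated inhibitor study
CELL_LINES = ("A375", "A549", "HA1E", "HCC515", "HEPG2", "HT29", "MCF7", "PC3")


@dataclass
class PerturbationSim:
    experiment: pd.DataFrame  # long format
    glycolysis_genes: tuple[str, ...]
    oxphos_genes: tuple[str, ...]
    seed: int


def generate_perturbation(
    n_genes_glyc: int = 52,
    n_genes_oxphos: int = 116,
    n_reps_control: int = 10,
    n_reps_treated: int = 4,
    delta_glyc: float = 1.0,
    delta_ox: float = 0.0,
    sigma: float = 0.2,
    *,
    cell_lines: tuple[str, ...] = CELL_LINES,
    shifted_lines: tuple[str, ...] = (),
    baseline_shift: float = 0.0,
    seed: int = 0,
) -> PerturbationSim:
    """Simulate paired control/treated replicate tables.

    Per cell line and gene a baseline ~ N(0,1) is drawn (cell lines in
    ``shifted_lines`` get ``baseline_shift`` added to OXPHOS-gene baselines,
    for baseline-characterization tests). Control replicates scatter
    N(baseline, sigma); treated replicates are baseline - ``delta_glyc`` on
    glycolysis genes and baseline + ``delta_ox`` on OXPHOS genes, plus the
    same noise. Identical seeds give identical tables.
    """
    if n_reps_control < 2 or n_reps_treated < 2:
        raise ValueError("need >= 2 replicates per arm")
    rng = np.random.default_rng(seed)
    glyc = tuple(f"GLY{i:03d}" for i in range(1, n_genes_glyc + 1))
    oxph = tuple(f"OXP{i:03d}" for i in range(1, n_genes_oxphos + 1))
    genes = glyc + oxph
    shift = np.concatenate(
        [np.full(len(glyc), -delta_glyc), np.full(len(oxph), delta_ox)]
    )

    rows = []
    for line in cell_lines:
        baseline = rng.standard_normal(len(genes))
        if line in shifted_lines:
            baseline[len(glyc):] += baseline_shift
        for condition, n_reps, offset in (
            ("control", n_reps_control, 0.0),
            ("treated", n_reps_treated, shift),
        ):
            for r in range(1, n_reps + 1):
                vals = baseline + offset + rng.normal(0.0, sigma, len(genes))
                rows.extend(
                    {
                        "cell_line": line,
                        "condition": condition,
                        "replicate": f"r{r}",
                        "gene": g,
                        "value": v,
                    }
                    for g, v in zip(genes, vals)
                )
    return PerturbationSim(
        pd.DataFrame(rows, columns=["cell_line", "condition", "replicate", "gene", "value"]),
        glyc,
        oxph,
        seed,
    )
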