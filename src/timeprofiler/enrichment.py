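"""Mutation-frequency filtering and the Fisher-exact enrichment screen.

The screen asks, per gene, whether the *patient-level* mutation frequency
differs across the three TIME subtypes. Record counts (which may include
several mutations of one gene in one patient) feed only the >=10-record
inclusion filter; contingency tables always use mutated-patient status.

The omnibus test on the 2x3 (mutation status x subtype) table is the
Freeman-Halton extension of Fisher's exact test, computed by exhaustive
enumeration of tables with the observed margins: two-sided p is the total
probability of tables no more probable than the observed one (the
point-probability rule). The mutated-row margin is small in practice, so
enumeration is cheap. 2x2 tests use the same rule (scipy's two-sided
``fisher_exact``).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_genes",
    "fisher_exact_2x2",
    "fisher_exact_2x3",
    "enrichment_screen",
    "cytact_association",
    "domain_tabulation",
]

#: relative tolerance when comparing table probabilities (R's convention):
#: a table counts as "as extreme" if P(table) <= P(observed) * (1 + 1e-7).
_REL_TOL = 1e-7


def filter_genes(mut, min_count: int = 10) -> pd.DataFrame:
    """Per-gene mutation statistics for genes with >= ``min_count`` records.

    Returns a DataFrame with columns ``gene``, ``mutation_count`` (records),
    ``mutated_patient_count``, ``patient_frequency`` and ``count_frequency``
    (both relative to the number of profiled samples), sorted by record count
    descending with alphabetical tie-break.
    """
    if mut.n_profiled == 0:
        raise ValueError("no profiled samples")
    n = mut.n_profiled
    grouped = mut.records.groupby("gene")
    rows = []
    for gene, sub in grouped:
        n_records = len(sub)
        if n_records < min_count:
            continue
        n_patients = sub["sample_id"].nunique()
        rows.append(
            {
                "gene": gene,
                "mutation_count": n_records,
                "mutated_patient_count": n_patients,
                "patient_frequency": n_patients / n,
                "count_frequency": n_records / n,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "mutation_count",
            "mutated_patient_count",
            "patient_frequency",
            "count_frequency",
        ],
    )
    if len(out):
        out = out.sort_values(
            ["mutation_count", "gene"], ascending=[False, True]
        ).reset_index(drop=True)
    return out


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table -> (odds ratio, p).

    Point-probability rule: p sums hypergeometric probabilities of all tables
    (same margins) no more probable than the observed one. A zero margin
    makes every table equally (un)informative: p = 1, odds ratio NaN.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def fisher_exact_2x3(table) -> float:
    """Freeman-Halton exact test on a 2x3 table -> two-sided p.

    Exhaustively enumerates all tables with the observed margins; p is the
    summed probability of tables whose conditional (multivariate
    hypergeometric) probability does not exceed the observed table's.
    Any zero row margin gives p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 3) or (t < 0).any():
        raise ValueError("need a nonnegative 2x3 table")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())
    if row.min() == 0 or n == 0:
        return 1.0

    # log P(table | margins) = sum(log r_i!) + sum(log c_j!) - log n! - sum(log x_ij!)
    base = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n + 1)

    def logp(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        c = row[0] - a - b
        cells = np.stack(
            [a, b, c, col[0] - a, col[1] - b, col[2] - c], axis=0
        )
        return base - gammaln(cells + 1).sum(axis=0)

    m = int(row[0])
    a_vals = np.arange(max(0, m - col[1] - col[2]), min(m, col[0]) + 1)
    pairs_a = []
    pairs_b = []
    for a in a_vals:
        b_lo = max(0, m - a - col[2])
        b_hi = min(m - a, col[1])
        if b_hi < b_lo:
            continue
        bs = np.arange(b_lo, b_hi + 1)
        pairs_a.append(np.full_like(bs, a))
        pairs_b.append(bs)
    all_a = np.concatenate(pairs_a)
    all_b = np.concatenate(pairs_b)
    lp = logp(all_a, all_b)
    lp_obs = logp(np.array([t[0, 0]]), np.array([t[0, 1]]))[0]
    keep = lp <= lp_obs + np.log1p(_REL_TOL)
    return float(min(1.0, np.exp(lp[keep]).sum()))


@dataclass
class EnrichmentResult:
    """Per-gene enrichment of mutations across the three subtypes."""

    gene: str
    counts: pd.DataFrame  # index mutated/wildtype, columns subtypes
    omnibus_p: float
    pairwise_p: dict[str, float]
    direction: str | None
    significant: bool
    q_value: float = float("nan")


def enrichment_screen(
    assignment: pd.Series,
    mut,
    genes: Sequence[str] | None = None,
    alpha: float = 0.05,
    *,
    min_count: int = 10,
    hpv_status: pd.Series | None = None,
) -> pd.DataFrame | dict[str, pd.DataFrame]:
    """Per-gene Fisher screen of mutation status against TIME subtype.

    Only classified samples enter the contingency tables. ``genes`` defaults
    to the >= ``min_count``-record genes from :func:`filter_genes`. When
    ``hpv_status`` is given the screen additionally runs inside the
    HPV-positive and HPV-negative strata and a dict of three DataFrames is
    returned (keys ``all``, ``hpv_positive``, ``hpv_negative``).

    Columns: per-subtype mutated/wildtype counts, ``omnibus_p`` (2x3
    Freeman-Halton), one pairwise 2x2 p per subtype (subtype vs pooled
    others), ``direction`` (subtype with the highest mutated fraction),
    ``significant`` (raw omnibus p < alpha) and Benjamini-Hochberg ``q``.
    """
    from .classify import SUBTYPES  # local import to avoid a cycle

    if hpv_status is not None:
        out: dict[str, pd.DataFrame] = {}
        out["all"] = enrichment_screen(
            assignment, mut, genes, alpha, min_count=min_count
        )
        for label in ("positive", "negative"):
            ids = hpv_status.index[hpv_status == label]
            sub = assignment.loc[assignment.index.intersection(ids)]
            out[f"hpv_{label}"] = enrichment_screen(
                sub, mut, genes, alpha, min_count=min_count
            )
        return out

    classified = assignment[assignment != "unclassified"]
    group_ids = {s: set(classified.index[classified == s]) for s in SUBTYPES}
    nonempty = [s for s in SUBTYPES if group_ids[s]]
    if len(nonempty) < 2:
        raise ValueError("enrichment screen needs >= 2 nonempty subtypes")
    sizes = {s: len(group_ids[s]) for s in SUBTYPES}

    if genes is None:
        genes = list(filter_genes(mut, min_count)["gene"])

    mutated_by_gene = {
        g: set(sub["sample_id"])
        for g, sub in mut.records.groupby("gene")
        if g in set(genes)
    }

    rows = []
    for gene in genes:
        mutated = mutated_by_gene.get(gene, set())
        m = {s: len(mutated & group_ids[s]) for s in SUBTYPES}
        w = {s: sizes[s] - m[s] for s in SUBTYPES}
        table = np.array(
            [[m[s] for s in SUBTYPES], [w[s] for s in SUBTYPES]], dtype=np.int64
        )
        total_mut = int(table[0].sum())
        if total_mut == 0:
            omnibus_p = 1.0
            direction = None
        else:
            omnibus_p = fisher_exact_2x3(table)
            fracs = {
                s: (m[s] / sizes[s] if sizes[s] else -1.0) for s in SUBTYPES
            }
            direction = max(SUBTYPES, key=lambda s: fracs[s])
        row = {
            "gene": gene,
            **{f"mut_{s}": m[s] for s in SUBTYPES},
            **{f"wt_{s}": w[s] for s in SUBTYPES},
            "omnibus_p": omnibus_p,
            "direction": direction,
        }
        for s in SUBTYPES:
            pair = [
                [m[s], total_mut - m[s]],
                [w[s], sum(w.values()) - w[s]],
            ]
            _, row[f"pairwise_p_{s}"] = fisher_exact_2x2(pair)
        rows.append(row)

    out_df = pd.DataFrame(rows)
    if len(out_df):
        out_df["significant"] = out_df["omnibus_p"] < alpha
        out_df["q_value"] = multipletests(
            out_df["omnibus_p"].to_numpy(), method="fdr_bh"
        )[1]
    return out_df


def cytact_association(
    mut_status: pd.Series, cytact: pd.Series
) -> tuple[np.ndarray, float]:
    """Fisher 2x2 of one gene's mutation status against the CytAct call.

    Only CytAct ``up`` / ``down`` samples enter; ``neither`` is excluded.
    Returns ([[mut_up, mut_down], [wt_up, wt_down]], two-sided p).
    """
    common = mut_status.index.intersection(cytact.index)
    used = cytact.loc[common].isin(["up", "down"])
    if not used.any():
        raise ValueError("no samples with a CytAct up/down call")
    ids = common[used]
    mut = mut_status.loc[ids].astype(bool)
    up = cytact.loc[ids] == "up"
    table = np.array(
        [
            [int((mut & up).sum()), int((mut & ~up).sum())],
            [int((~mut & up).sum()), int((~mut & ~up).sum())],
        ]
    )
    _, p = fisher_exact_2x2(table)
    return table, p


def domain_tabulation(records: pd.DataFrame) -> pd.DataFrame:
    """Per-protein-domain mutation counts and CytAct-up percentages.

    ``records`` needs columns ``domain`` (free text; unknown/missing labels
    are bucketed as ``other``) and ``cytact_up`` (boolean: the carrying tumor
    had upregulated cytolytic activity). Domains without mutations do not
    appear. Percentages are rounded to 1 decimal place.
    """
    df = records.copy()
    df["domain"] = df.get("domain", pd.Series(dtype=str))
    df["domain"] = df["domain"].where(
        df["domain"].notna() & (df["domain"].astype(str).str.len() > 0), "other"
    )
    rows = []
    for domain, sub in df.groupby("domain"):
        total = len(sub)
        up = int(sub["cytact_up"].astype(bool).sum())
        rows.append(
            {
                "domain": domain,
                "n_mutations": total,
                "n_cytact_up": up,
                "percent_cytact_up": round(100.0 * up / total, 1),
            }
        )
    return pd.DataFrame(rows).sort_values("domain").reset_index(drop=True)
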