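"""Glycolysis vs OXPHOS phenotype across regulator-expression strata.

Splits the cohort into regulator-high/-low expressers (|z| >= 1), computes
per-gene upregulation frequencies for the 24-gene glycolysis and 31-gene
OXPHOS panels, Fisher per-gene comparisons, Welch panel-level tests, the
relative (share-normalized) phenotype, and word-cloud weight exports.
"""

import argparse
from pathlib import Path

from timeprofiler.classify import stratify_expression
from timeprofiler.core import load_expression, zscore
from timeprofiler.enrichment import fisher_exact_2x2
from timeprofiler.metabolism import (
    compare_gene_upregulation,
    compare_panel_means,
    default_panels,
    export_wordcloud_weights,
    relative_phenotype,
    upregulation_profile,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--outdir", type=Path, default=Path("results"))
parser.add_argument("--gene", default="EP300")
parser.add_argument("--kappa", type=float, default=1.0)
args = parser.parse_args()

z = zscore(load_expression(args.cohort / "expression.tsv"))
strata = stratify_expression(z, args.gene, args.kappa)
print(f"strata on {args.gene} at kappa={args.kappa}: "
      f"{strata.value_counts().to_dict()}")

panels = default_panels()
profile = upregulation_profile(z, panels, strata)
profile.table.to_csv(args.outdir / "metabolic_profile.tsv", sep="\t", index=False)

n_sig = sum(compare_gene_upregulation(profile, g)[1] < 0.05
            for g in panels.glycolysis)
print(f"{n_sig}/24 glycolysis genes differ between strata (Fisher p < 0.05)")

for panel in ("glycolysis", "oxphos"):
    res = compare_panel_means(profile, panel)
    print(f"{panel}: mean up-fraction high={res.mean_high:.3f} "
          f"low={res.mean_low:.3f}, Welch t={res.t_statistic:.2f}, "
          f"p={res.p_value:.2e}")

shares = relative_phenotype(profile)
shares.to_csv(args.outdir / "relative_phenotype.tsv", sep="\t", index=False)
print(shares.round(3).to_string(index=False))

for stratum in ("high", "low"):
    export_wordcloud_weights(profile, stratum,
                             args.outdir / f"wordcloud_{stratum}.tsv")
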