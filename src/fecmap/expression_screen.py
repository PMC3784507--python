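"""Efficiency-corrected qPCR relative quantification and genotype contrast.

Expression is quantified against a single reference gene with the
efficiency-corrected ratio R = E_ref^Ct_ref / E_target^Ct_target, where
E is the per-cycle amplification factor estimated from a dilution-series
slope via E = exp(-1/slope) (a log10 dilution scale variant,
E = 10^(-1/slope), is available through ``log10_dilutions=True``).
Ratios are computed per sample and then averaged per group; the
mutant/wild-type contrast is a two-sided Welch t-test on the ratio
scale (optionally on log ratios). Differences with p > 0.05 are treated
as not significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import NON_OVARIAN_TISSUES, OVARIAN_TISSUES

ALPHA = 0.05


def efficiency_from_slope(slope: float, log10_dilutions: bool = False) -> float:
    """Amplification efficiency from the Ct-vs-log-dilution slope.

    E = exp(-1/slope) on a natural-log dilution scale (the default), or
    10^(-1/slope) for log10 dilution series.
    """
    if not slope < 0:
        raise ValueError("dilution-series slope must be negative")
    base = 10.0 if log10_dilutions else math.e
    return base ** (-1.0 / slope)


def slope_from_efficiency(e: float, log10_dilutions: bool = False) -> float:
    if e <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    base = 10.0 if log10_dilutions else math.e
    return -1.0 / math.log(e, base)


def relative_expression(
    ct_target: float, ct_ref: float, e_target: float, e_ref: float
) -> float:
    """Efficiency-corrected ratio R = E_ref^Ct_ref / E_target^Ct_target.

    Multiply by 100 for the conventional percentage view. Strictly
    decreasing in Ct_target and increasing in Ct_ref.
    """
    if e_target <= 1 or e_ref <= 1:
        raise ValueError("amplification efficiencies must exceed 1")
    if not (math.isfinite(ct_target) and math.isfinite(ct_ref)):
        raise ValueError("Ct values must be finite")
    # compute in log space to survive large Ct differences
    return math.exp(ct_ref * math.log(e_ref) - ct_target * math.log(e_target))


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test p-value with explicit zero-variance handling."""
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


@dataclass(frozen=True)
class GenotypeContrast:
    gene: str
    tissue: str
    fold_change: float  # mean mutant R over mean wild-type R
    p_value: float | None
    mean_wt: float
    sem_wt: float
    mean_mut: float
    sem_mut: float
    n_wt: int
    n_mut: int

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value < ALPHA

    @property
    def stars(self) -> str:
        if self.p_value is None or self.p_value >= ALPHA:
            return ""
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        return "*"


def sample_ratios(
    measurements: pd.DataFrame,
    efficiencies: Mapping[str, float],
    reference_gene: str = "RPL19",
) -> pd.DataFrame:
    """Per-sample efficiency-corrected ratios for every non-reference gene.

    ``measurements`` needs columns sample/tissue/genotype/gene/ct with
    exactly one reference-gene Ct per sample.
    """
    ref = measurements[measurements["gene"] == reference_gene]
    ref_ct = ref.set_index("sample")["ct"]
    if ref_ct.index.has_duplicates:
        raise ValueError("multiple reference-gene measurements per sample")
    rows = []
    for row in measurements[measurements["gene"] != reference_gene].itertuples():
        if row.sample not in ref_ct.index:
            raise ValueError(f"sample {row.sample!r} lacks a reference Ct")
        r = relative_expression(
            row.ct,
            float(ref_ct[row.sample]),
            efficiencies[row.gene],
            efficiencies[reference_gene],
        )
        rows.append((row.sample, row.tissue, row.genotype, row.gene, r))
    return pd.DataFrame(
        rows, columns=["sample", "tissue", "genotype", "gene", "ratio"]
    )


def compare_genotypes(
    measurements: pd.DataFrame,
    gene: str,
    tissue: str,
    efficiencies: Mapping[str, float],
    reference_gene: str = "RPL19",
    log_scale: bool = False,
) -> GenotypeContrast:
    """Mutant-vs-wild-type expression contrast for one gene and tissue.

    Per-sample ratios first, then group means; fold = mean(L/L) /
    mean(+/+); Welch two-sided t-test on the ratios (or their logs with
    ``log_scale``). With fewer than two samples in a group the p-value
    is undefined (None) and flagged by ``significant`` being False.
    """
    sub = measurements[
        (measurements["gene"].isin([gene, reference_gene]))
        & (measurements["tissue"] == tissue)
    ]
    ratios = sample_ratios(sub, efficiencies, reference_gene)
    wt = ratios.loc[ratios["genotype"] == "+/+", "ratio"].to_numpy()
    mut = ratios.loc[ratios["genotype"] == "L/L", "ratio"].to_numpy()
    if wt.size == 0 or mut.size == 0:
        raise ValueError(f"missing genotype group for {gene} in {tissue}")
    fold = float(mut.mean() / wt.mean())
    if wt.size < 2 or mut.size < 2:
        p = None
    elif log_scale:
        p = _welch(np.log(mut), np.log(wt))
    else:
        p = _welch(mut, wt)
    sem = lambda x: float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else float("nan")
    return GenotypeContrast(
        gene, tissue, fold, p,
        float(wt.mean()), sem(wt), float(mut.mean()), sem(mut),
        int(wt.size), int(mut.size),
    )


def screen_expression_candidates(
    measurements: pd.DataFrame,
    interval_genes: Sequence[str],
    flanking_genes: Sequence[str],
    efficiencies: Mapping[str, float],
    reference_gene: str = "RPL19",
    ovarian_tissues: Sequence[str] = OVARIAN_TISSUES,
) -> pd.DataFrame:
    """Rank ectopic-expression candidates among positional genes.

    A gene qualifies when its genotype contrast is significant in at
    least one ovarian tissue and non-significant in every non-ovarian
    tissue measured — the signature of an ovary-restricted regulatory
    effect rather than a global one. Candidates are ranked by their
    maximal ovarian fold change; non-candidates are returned too, with
    ``candidate = False``.
    """
    tissues = measurements["tissue"].unique()
    genes = [g for g in (*interval_genes, *flanking_genes) if g != reference_gene]
    rows = []
    for gene in genes:
        present = measurements[measurements["gene"] == gene]["tissue"].unique()
        contrasts = {
            t: compare_genotypes(
                measurements, gene, t, efficiencies, reference_gene
            )
            for t in tissues
            if t in present
        }
        ovarian = [c for t, c in contrasts.items() if t in ovarian_tissues]
        other = [c for t, c in contrasts.items() if t not in ovarian_tissues]
        is_candidate = any(c.significant for c in ovarian) and not any(
            c.significant for c in other
        )
        max_fold = max((c.fold_change for c in ovarian), default=float("nan"))
        rows.append(
            {
                "gene": gene,
                "in_interval": gene in interval_genes,
                "candidate": is_candidate,
                "max_ovarian_fold": max_fold,
                "significant_ovarian_tissues": sum(
                    c.significant for c in ovarian
                ),
                "significant_other_tissues": sum(c.significant for c in other),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["candidate", "max_ovarian_fold"], ascending=[False, False]
    ).reset_index(drop=True)
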