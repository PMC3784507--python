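"""Presence/absence and spectral-count filtering of protein identifications.

Consumes replicate-structured identification tables (protein accession,
replicate, genotype, distinct-peptide count, identification probability,
normalized spectral count, theoretical MW, peptide ids) and extracts the
proteins exclusively identified in one genotype's samples: retained in
every replicate of that genotype and in none of the other's, after the
probability and minimum-peptide thresholds. Spectra matching peptides
shared between proteins are discarded before counting, so quantification
rests on protein-distinct evidence only. Database searching and spectrum
scoring are upstream concerns and out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = (
    "protein", "replicate", "genotype", "n_peptides", "probability",
    "spectral_count", "mw_kda",
)


def _check(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"identification table lacks columns: {missing}")


def drop_shared_peptides(records: pd.DataFrame) -> pd.DataFrame:
    """Remove evidence from peptides mapped to more than one protein.

    The ``peptides`` column holds ';'-separated peptide ids. A peptide
    assigned to >= 2 distinct proteins (anywhere in the table) counts for
    none of them: ``n_peptides`` becomes the distinct-peptide count of
    the exclusive peptides and ``spectral_count`` is rescaled by the
    retained fraction. Idempotent; a table with no shared peptides is
    returned unchanged in content.
    """
    _check(records)
    if "peptides" not in records.columns:
        return records.copy()
    out = records.copy()
    pep_lists = out["peptides"].fillna("").str.split(";")
    owners: dict[str, set[str]] = {}
    for protein, peps in zip(out["protein"], pep_lists):
        for p in peps:
            if p:
                owners.setdefault(p, set()).add(protein)
    shared = {p for p, o in owners.items() if len(o) > 1}
    new_counts = []
    new_spectra = []
    new_peps = []
    for peps, n_pep, sc in zip(pep_lists, out["n_peptides"], out["spectral_count"]):
        distinct = [p for p in dict.fromkeys(peps) if p]
        kept = [p for p in distinct if p not in shared]
        frac = len(kept) / len(distinct) if distinct else 0.0
        new_counts.append(len(kept))
        new_spectra.append(sc * frac)
        new_peps.append(";".join(kept))
    out["n_peptides"] = new_counts
    out["spectral_count"] = new_spectra
    out["peptides"] = new_peps
    return out


def filter_identifications(
    records: pd.DataFrame,
    min_peptides: int = 4,
    min_probability: float = 0.95,
) -> pd.DataFrame:
    """Retain identifications with probability strictly above
    ``min_probability`` and at least ``min_peptides`` distinct peptides."""
    _check(records)
    keep = (records["probability"] > min_probability) & (
        records["n_peptides"] >= min_peptides
    )
    return records[keep].reset_index(drop=True)


def genotype_exclusive(
    retained: pd.DataFrame,
    exclusive_genotype: str = "L/L",
    other_genotype: str = "+/+",
    required_replicates: int = 2,
) -> pd.DataFrame:
    """Proteins identified in every replicate of one genotype and in no
    replicate of the other.

    Returns one row per exclusive protein with its MW and the mean
    spectral count in the exclusive genotype.
    """
    _check(retained)
    rows = []
    for protein, grp in retained.groupby("protein", sort=True):
        reps_excl = set(grp.loc[grp["genotype"] == exclusive_genotype, "replicate"])
        reps_other = set(grp.loc[grp["genotype"] == other_genotype, "replicate"])
        if len(reps_excl) >= required_replicates and not reps_other:
            sub = grp[grp["genotype"] == exclusive_genotype]
            rows.append(
                {
                    "protein": protein,
                    "gene_symbol": sub["gene_symbol"].iloc[0]
                    if "gene_symbol" in sub
                    else protein,
                    "mw_kda": float(sub["mw_kda"].iloc[0]),
                    "mean_spectral_count": float(sub["spectral_count"].mean()),
                    "n_replicates": len(reps_excl),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "protein", "gene_symbol", "mw_kda", "mean_spectral_count",
            "n_replicates",
        ],
    )


def normalize_spectral_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Scale each (genotype, replicate) column so every replicate's total
    spectral count equals the across-replicate mean total; preserves the
    within-replicate ordering of counts."""
    _check(records)
    out = records.copy()
    totals = out.groupby(["genotype", "replicate"])["spectral_count"].transform("sum")
    grand = out.groupby(["genotype", "replicate"])["spectral_count"].sum().mean()
    out["spectral_count"] = out["spectral_count"] * grand / totals
    return out


def spectral_count_test(
    records: pd.DataFrame,
    genotype_a: str = "+/+",
    genotype_b: str = "L/L",
) -> pd.DataFrame:
    """Per-protein two-sided t-test on normalized spectral counts.

    Proteins absent from a replicate contribute a zero count. With fewer
    than two replicates in a group the p-value is undefined (NaN,
    ``testable`` False); zero variance in both groups with equal means
    gives p = 1.
    """
    _check(records)
    reps = {
        g: sorted(records.loc[records["genotype"] == g, "replicate"].unique())
        for g in (genotype_a, genotype_b)
    }
    rows = []
    for protein, grp in records.groupby("protein", sort=True):
        counts = {}
        for g in (genotype_a, genotype_b):
            by_rep = grp[grp["genotype"] == g].set_index("replicate")[
                "spectral_count"
            ]
            counts[g] = np.array([float(by_rep.get(r, 0.0)) for r in reps[g]])
        a, b = counts[genotype_a], counts[genotype_b]
        if a.size < 2 or b.size < 2:
            p, testable = float("nan"), False
        elif a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            p, testable = (1.0 if a.mean() == b.mean() else 0.0), True
        else:
            p, testable = float(stats.ttest_ind(a, b, equal_var=False).pvalue), True
        rows.append(
            {
                "protein": protein,
                "mean_a": a.mean() if a.size else float("nan"),
                "mean_b": b.mean() if b.size else float("nan"),
                "p_value": p,
                "testable": testable,
                "significant": testable and p < 0.05,
            }
        )
    return pd.DataFrame(rows)


def mw_summary(exclusive: pd.DataFrame) -> tuple[float, float]:
    """(min, max) theoretical MW in kDa over an exclusive protein set."""
    if len(exclusive) == 0:
        raise ValueError("empty exclusive protein set")
    mw = exclusive["mw_kda"].astype(float)
    if mw.isna().any():
        raise ValueError("missing MW annotation")
    return float(mw.min()), float(mw.max())
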