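"""End-to-end orchestration: simulate (or replay) every stage and emit a
deterministic, fully seeded report bundle.

Two entry points:

* :func:`run_pipeline` — forward-simulate a study under a
  :class:`~fecmap.synthetic_data.SimulationConfig` and push it through
  carrier classification, pedigree phasing, recombinant interval
  reduction, sequence diffing, the staged allele screen, the qPCR
  expression screen and the MS presence/absence filter.
* :func:`replay_published` — rerun the same computations on the packaged
  printed tables (marker coordinates, polymorphism/allele-sharing list,
  primer efficiencies, protein identifications), reproducing the locus
  arithmetic and candidate sets without any simulation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .allele_screen import fully_associated, staged_screen
from .expression_screen import screen_expression_candidates
from .genome_model import format_kb, interval_span
from .ms_differential import (
    drop_shared_peptides,
    filter_identifications,
    genotype_exclusive,
    mw_summary,
    normalize_spectral_counts,
    spectral_count_test,
)
from .recombinant_mapping import (
    assign_carrier_chromosomes,
    detect_recombinants,
    phase_by_descent,
    reduce_interval,
)
from .synthetic_data import (
    ExpressionDesign,
    MsDesign,
    ORModel,
    PanelSpec,
    PedigreeDesign,
    SimulationConfig,
    pedigree_phenotypes,
    simulate_founders,
    simulate_panels,
    simulate_pedigree,
    simulate_qpcr,
    simulate_sequence_pair,
    simulate_ms_table,
    substream,
)
from .variant_discovery import diff_haplotypes, summarize_variants, write_vcf

log = logging.getLogger("fecmap")

DEFAULT_EFFICIENCY = 2.0


class PipelineError(RuntimeError):
    pass


def config_from_dict(d: Mapping[str, Any]) -> SimulationConfig:
    """Build a SimulationConfig from a (YAML-derived) nested mapping;
    unknown keys raise rather than being ignored."""
    d = dict(d)
    kwargs: dict[str, Any] = {}
    nested = {
        "pedigree": PedigreeDesign,
        "or_model": ORModel,
        "expression": ExpressionDesign,
        "ms": MsDesign,
    }
    for key, cls in nested.items():
        if key in d:
            kwargs[key] = cls(**d.pop(key))
    if "panels" in d:
        kwargs["panels"] = tuple(PanelSpec(**p) for p in d.pop("panels"))
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - fields
    if unknown:
        raise PipelineError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs.update(d)
    return SimulationConfig(**kwargs)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def _expression_inputs(
    config: SimulationConfig,
) -> tuple[ExpressionDesign, dict[str, float]]:
    """Extend the expression design with fold-1 flanking genes and fill in
    efficiencies (packaged values where known, a default of 2.0 else)."""
    folds = {g: dict(t) for g, t in config.expression.fold_changes.items()}
    for gene in datasets.FLANKING_GENES:
        folds.setdefault(gene, {})
    design = dataclasses.replace(config.expression, fold_changes=folds)
    eff = dict(datasets.load_efficiencies())
    for gene in (*folds, design.reference_gene):
        eff.setdefault(gene, DEFAULT_EFFICIENCY)
    return design, eff


def run_pipeline(config: SimulationConfig) -> dict[str, Any]:
    """Execute every stage on a synthetic study; returns the report dict.

    Deterministic for a fixed ``config.seed``: each stage consumes its
    own named substream of the master seed.
    """
    if config.pedigree.total == 0:
        raise PipelineError(
            "no informative meioses: the pedigree design has zero animals"
        )
    report: dict[str, Any] = {
        "seed": config.seed,
        "config": _jsonable(dataclasses.asdict(config)),
        "stages": {},
    }

    pool = simulate_founders(config, substream(config.seed, "founders"))
    positions = np.asarray(pool.marker_map.positions)
    causal_pos = int(positions[pool.causal_index])
    log.info("founders: %d wild lineages + L", config.n_wild_founders)

    pedigree = simulate_pedigree(config, pool, substream(config.seed, "pedigree"))
    non_founders = pedigree.non_founders
    report["stages"]["pedigree"] = {
        "n_animals": len(non_founders),
        "n_founders": len(pedigree.animals) - len(non_founders),
        "class_counts": dict(
            pd.Series([a.observed_class for a in non_founders])
            .value_counts()
            .sort_index()
        ),
    }

    phenotypes = pedigree_phenotypes(
        pedigree, config.or_model, substream(config.seed, "phenotypes")
    )
    by_class = phenotypes.groupby("genotype")["ovulation_rate"].mean()
    report["stages"]["phenotypes"] = {
        "mean_or_by_class": {k: float(v) for k, v in by_class.items()}
    }

    phased = phase_by_descent(pedigree)
    chroms = assign_carrier_chromosomes(phased, pedigree)
    recombinants = detect_recombinants(chroms, pool.marker_map)
    region = (1, config.region_length)
    interval, zones = reduce_interval(chroms, pool.marker_map, region)
    report["stages"]["mapping"] = {
        "n_constraint_chromosomes": len(chroms),
        "n_recombinants": len(recombinants),
        "interval": {
            "start_bp": interval.start_bp,
            "end_bp": interval.end_bp,
            "span_bp": interval.span,
            "span_kb": format_kb(interval.span),
            "proximal_marker": interval.proximal_marker,
            "distal_marker": interval.distal_marker,
        },
        "causal_position": causal_pos,
        "causal_in_interval": bool(
            interval.start_bp <= causal_pos <= interval.end_bp
        ),
    }

    # sequence-level variant discovery over a synthetic haplotype pair
    wild_seq, mutant_seq, planted = simulate_sequence_pair(
        4000, substream(config.seed, "sequences"), n_snp=5, n_microsat=2, n_indel=2
    )
    calls = diff_haplotypes(wild_seq, mutant_seq)
    report["stages"]["variants"] = {
        "planted": len(planted),
        "called": summarize_variants(calls),
    }

    panels = simulate_panels(config, pool, substream(config.seed, "panels"))
    in_interval = [
        i
        for i, p in enumerate(positions)
        if interval.start_bp <= p <= interval.end_bp
    ]
    records = [
        staged_screen(
            pool.marker_map.ids[i],
            i,
            l_allele=1,
            panels=panels,
            is_border=int(positions[i])
            in (interval.start_bp, interval.end_bp),
        )
        for i in in_interval
    ]
    associated = fully_associated(records)
    causal_id = pool.marker_map.ids[pool.causal_index]
    report["stages"]["allele_screen"] = {
        "n_screened": len(records),
        "n_excluded": sum(r.excluded for r in records),
        "fully_associated": sorted(r.poly_id for r in associated),
        "causal_id": causal_id,
        "causal_fully_associated": any(
            r.poly_id == causal_id for r in associated
        ),
    }

    design, efficiencies = _expression_inputs(config)
    qpcr = simulate_qpcr(design, efficiencies, substream(config.seed, "qpcr"))
    expr = screen_expression_candidates(
        qpcr,
        interval_genes=list(config.expression.fold_changes),
        flanking_genes=list(datasets.FLANKING_GENES),
        efficiencies=efficiencies,
        reference_gene=design.reference_gene,
    )
    report["stages"]["expression"] = {
        "candidates": expr.loc[expr["candidate"], "gene"].tolist(),
    }

    ms_raw = simulate_ms_table(config.ms, substream(config.seed, "ms"))
    ms = normalize_spectral_counts(drop_shared_peptides(ms_raw))
    retained = filter_identifications(ms)
    exclusive = genotype_exclusive(
        retained, required_replicates=config.ms.replicates
    )
    report["stages"]["ms"] = {
        "n_identifications": len(ms_raw),
        "n_exclusive": len(exclusive),
        "mw_range_kda": list(mw_summary(exclusive)) if len(exclusive) else None,
    }

    report["_tables"] = {
        "pedigree": pedigree.to_frame(),
        "genotypes": pedigree.genotype_frame(),
        "phenotypes": phenotypes,
        "recombinants": pd.DataFrame([dataclasses.asdict(r) for r in recombinants]),
        "share_records": pd.DataFrame([dataclasses.asdict(r) for r in records]),
        "qpcr": qpcr,
        "expression": expr,
        "ms_exclusive": exclusive,
        "ms_sc_test": spectral_count_test(retained),
    }
    report["_artifacts"] = {
        "interval": interval,
        "zones": zones,
        "variant_calls": calls,
        "wild_seq": wild_seq,
    }
    return report


def replay_published() -> dict[str, Any]:
    """Re-derive the headline numbers from the packaged printed tables."""
    report: dict[str, Any] = {"stages": {}}

    spans = {
        "initial_interval_bp": interval_span(datasets.GNGT2_M2, datasets.MS162),
        "reduced_interval_bp": interval_span(
            datasets.BORDER_PROXIMAL, datasets.BORDER_DISTAL
        ),
        "candidate_snp_gap_bp": interval_span(
            datasets.CANDIDATE_SNP_1, datasets.CANDIDATE_SNP_2
        ),
        "locus_length_bp": interval_span(
            1, datasets.LOCUS_DISTAL_BORDER_LOCUS_POS
        ),
    }
    report["stages"]["intervals"] = {
        **spans,
        "initial_interval_kb": format_kb(spans["initial_interval_bp"]),
        "reduced_interval_kb": format_kb(spans["reduced_interval_bp"]),
        "candidate_snp_gap_kb": format_kb(spans["candidate_snp_gap_bp"]),
        "locus_length_kb": format_kb(spans["locus_length_bp"], precision=1),
    }

    polys = datasets.table1_polymorphisms()
    records = datasets.table1_share_records()
    associated = fully_associated(records)
    report["stages"]["polymorphisms"] = {
        "counts": summarize_variants(polys),
        "fully_associated": sorted(r.poly_id for r in associated),
        "fully_associated_sharing": sorted(r.sharing for r in associated),
    }

    design = ExpressionDesign(ct_noise_sd=0.0)
    design, efficiencies = _expression_inputs(
        SimulationConfig(expression=design)
    )
    qpcr = simulate_qpcr(design, efficiencies, np.random.default_rng(0), noise_sd=0.0)
    expr = screen_expression_candidates(
        qpcr,
        interval_genes=["B4GALNT2", "IGF2BP1"],
        flanking_genes=list(datasets.FLANKING_GENES),
        efficiencies=efficiencies,
    )
    report["stages"]["expression"] = {
        "candidates": expr.loc[expr["candidate"], "gene"].tolist(),
        "max_folds": dict(
            zip(expr["gene"], (float(f) for f in expr["max_ovarian_fold"]))
        ),
    }

    ms = datasets.load_ms_identifications()
    retained = filter_identifications(drop_shared_peptides(ms))
    exclusive = genotype_exclusive(retained)
    report["stages"]["ms"] = {
        "n_exclusive": len(exclusive),
        "exclusive_symbols": sorted(exclusive["gene_symbol"]),
        "mw_range_kda": list(mw_summary(exclusive)),
    }
    report["_tables"] = {"ms_exclusive": exclusive, "expression": expr}
    return report


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(report: Mapping[str, Any], outdir: str | Path) -> list[Path]:
    """Serialize a report bundle: JSON summary, per-stage TSVs, BED
    interval, VCF calls. Byte-stable for identical inputs (sorted keys,
    fixed float formatting)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary = {k: v for k, v in report.items() if not k.startswith("_")}
    path = out / "report.json"
    path.write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n")
    written.append(path)

    for name, df in report.get("_tables", {}).items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)

    artifacts = report.get("_artifacts", {})
    interval = artifacts.get("interval")
    if interval is not None:
        path = out / "interval.bed"
        # BED is 0-based half-open; closed 1-based (start, end) converts
        # to (start - 1, end)
        path.write_text(
            f"{interval.chrom}\t{interval.start_bp - 1}\t{interval.end_bp}"
            f"\tminimal_locus\n"
        )
        written.append(path)
    calls = artifacts.get("variant_calls")
    if calls is not None:
        path = out / "variants.vcf"
        with open(path, "w") as fh:
            write_vcf(calls, fh, wild_seq=artifacts.get("wild_seq"))
        written.append(path)
    return written
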