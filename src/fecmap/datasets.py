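"""Packaged fixture tables and locus landmarks.

The polymorphism/allele-sharing table, the exclusive-glycoprotein list
and the primer-efficiency table are shipped as TSV resources; this
module parses them into the pipeline's domain types. Landmark marker
coordinates on ovine chromosome 11 (OARv3.1) are the printed inputs of
the fine-mapping arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .allele_screen import ShareRecord
from .genome_model import Polymorphism, VariantType

CHROM = "OAR11"

# Landmark markers on OAR11 v3.1 (1-based bp).
GNGT2_M2 = 36899194  # proximal bound of the pre-sequencing interval
MS162 = 37387389  # distal bound of the pre-sequencing interval
BORDER_PROXIMAL = 36910171  # recombinant border SNP g.36910171T>C
BORDER_DISTAL = 37107627  # recombinant border SNP g.37107627G>C
CANDIDATE_SNP_1 = 36938224  # g.36938224T>A, B4GALNT2 intron 7
CANDIDATE_SNP_2 = 37034573  # g.37034573A>G, intergenic
LOCUS_DISTAL_BORDER_LOCUS_POS = 194639  # distal border on the sequenced locus

#: Genes inside the zero-recombinant minimal locus.
INTERVAL_GENES = ("B4GALNT2", "EZR", "IGF2BP1")
#: Flanking genes of the one-recombinant zones, screened for expression.
FLANKING_GENES = (
    "PHOSPHO1", "ABI3", "GNGT2", "GIP", "SNF8", "UBE2Z", "ATP5G1", "CALCOCO2",
)


def _read(name: str) -> pd.DataFrame:
    with resources.files("fecmap.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", dtype=str)


def load_polymorphism_table() -> pd.DataFrame:
    """The published polymorphism list with k/n allele sharing, verbatim."""
    df = _read("table1_polymorphisms.tsv")
    df["border"] = df["border"].astype(int).astype(bool)
    df["associated"] = df["associated"].astype(int).astype(bool)
    for col in ("ref_pos", "locus_pos"):
        df[col] = pd.to_numeric(df[col].replace(".", pd.NA), errors="raise")
    return df


def table1_polymorphisms() -> list[Polymorphism]:
    out = []
    for row in load_polymorphism_table().itertuples():
        ptype = VariantType(row.ptype)
        kwargs = dict(
            id=row.id,
            ptype=ptype,
            ref_pos=None if pd.isna(row.ref_pos) else int(row.ref_pos),
            locus_pos=None if pd.isna(row.locus_pos) else int(row.locus_pos),
        )
        if ptype is VariantType.MICROSAT:
            kwargs.update(
                motif=row.motif,
                wild_repeats=int(row.wild_repeats),
                mutant_repeats=None
                if row.mutant_repeats == "?"
                else int(row.mutant_repeats),
            )
        else:
            kwargs.update(
                wild_allele="" if row.wild_allele == "." else row.wild_allele,
                mutant_allele="" if row.mutant_allele == "." else row.mutant_allele,
            )
        out.append(Polymorphism(**kwargs))
    return out


def table1_share_records() -> list[ShareRecord]:
    """The printed cumulative k/n sharing as ShareRecords (stage unknown
    for printed rows; recorded as 0)."""
    out = []
    for row in load_polymorphism_table().itertuples():
        k, n = (int(x) for x in row.sharing.split("/"))
        out.append(
            ShareRecord(
                poly_id=row.id,
                k=k,
                n=n,
                stage=0,
                excluded=k > 0,
                is_border=bool(row.border),
            )
        )
    return out


def load_exclusive_proteins() -> pd.DataFrame:
    """Published list of the 10 L/L-exclusive glycoproteins with MW."""
    df = _read("table2_exclusive_proteins.tsv")
    df["mw_kda"] = df["mw_kda"].astype(float)
    return df


def load_ms_identifications() -> pd.DataFrame:
    """Replicate-level MS identification fixture (metadata published,
    replicate detail synthetic; see the file header)."""
    df = _read("ms_identifications_synthetic.tsv")
    for col, typ in (
        ("replicate", int),
        ("n_peptides", int),
        ("probability", float),
        ("spectral_count", float),
        ("mw_kda", float),
    ):
        df[col] = df[col].astype(typ)
    return df


def load_efficiencies() -> dict[str, float]:
    """Per-gene qPCR amplification efficiencies E."""
    df = _read("table3_efficiencies.tsv")
    return dict(zip(df["gene"], df["efficiency"].astype(float)))
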