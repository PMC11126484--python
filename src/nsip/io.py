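"""Tab-separated readers and writers for all pipeline tables.

All tables are TSV (UTF-8, '.' decimal). The fraction table carries one row
per (gene, treatment, replicate, fraction); buoyant density may be supplied
directly or as a refractive index, which is converted on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from nsip.community_summary import ZotuTable
from nsip.nitrogen_dynamics import ChemTimeSeries, SoilMetadata
from nsip.sip_quant import FractionProfile, LabelingEstimate, ri_to_bd

_FRACTION_KEY = ["soil", "gene", "treatment", "replicate"]


def write_fraction_table(profiles: Iterable[FractionProfile], path: str | Path) -> None:
    """Write fraction profiles as a TSV, one row per fraction."""
    rows = []
    for p in profiles:
        for idx, bd, copies in zip(p.fraction_index, p.buoyant_density, p.copies):
            rows.append(
                {
                    "soil": p.soil,
                    "gene": p.gene,
                    "treatment": p.treatment,
                    "replicate": p.replicate,
                    "fraction_index": idx,
                    "buoyant_density_g_ml": bd,
                    "copies_per_g": copies,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fraction_table(path: str | Path) -> list[FractionProfile]:
    """Read a fraction TSV into :class:`FractionProfile` objects.

    Requires columns gene, treatment, fraction_index, copies_per_g and one of
    buoyant_density_g_ml / refractive_index (RI is converted via
    :func:`~nsip.sip_quant.ri_to_bd`); soil and replicate are optional.
    Validates uniqueness and the contiguity of fraction indices per profile.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "treatment", "fraction_index", "copies_per_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "buoyant_density_g_ml" in df.columns:
        bd = df["buoyant_density_g_ml"].astype(float)
    elif "refractive_index" in df.columns:
        bd = df["refractive_index"].astype(float).map(ri_to_bd)
    else:
        raise ValueError(f"{path}: need buoyant_density_g_ml or refractive_index")
    df = df.assign(_bd=bd)
    for col, default in (("soil", ""), ("replicate", "1")):
        if col not in df.columns:
            df[col] = default
        df[col] = df[col].fillna(default)
    df["soil"] = df["soil"].astype(str)
    df["replicate"] = df["replicate"].astype(str)

    dup = df.duplicated(subset=_FRACTION_KEY + ["fraction_index"])
    if dup.any():
        first = df.loc[dup, _FRACTION_KEY + ["fraction_index"]].iloc[0].to_dict()
        raise ValueError(f"{path}: duplicate fraction row {first}")

    profiles = []
    for key, grp in df.groupby(_FRACTION_KEY, sort=True):
        soil, gene, treatment, replicate = key
        grp = grp.sort_values("fraction_index")
        idx = grp["fraction_index"].astype(int).tolist()
        expected = list(range(min(idx), min(idx) + len(idx)))
        if idx != expected:
            gap = sorted(set(expected) - set(idx))
            raise ValueError(
                f"{path}: profile {key} has non-contiguous fractions; missing {gap}"
            )
        profiles.append(
            FractionProfile(
                gene=gene,
                treatment=treatment,
                soil=soil,
                replicate=replicate,
                fraction_index=tuple(idx),
                buoyant_density=tuple(grp["_bd"].astype(float)),
                copies=tuple(grp["copies_per_g"].astype(float)),
            )
        )
    return profiles


def write_chem_table(series: Iterable[ChemTimeSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for day, nh4, no3 in zip(s.days, s.nh4, s.no3):
            rows.append(
                {
                    "soil": s.soil,
                    "treatment": s.treatment,
                    "replicate": s.replicate,
                    "day": day,
                    "nh4_mg_kg": nh4,
                    "no3_mg_kg": no3,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_chem_table(path: str | Path) -> list[ChemTimeSeries]:
    df = pd.read_csv(path, sep="\t")
    required = {"treatment", "replicate", "day", "nh4_mg_kg", "no3_mg_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "soil" not in df.columns:
        df["soil"] = ""
    df["soil"] = df["soil"].fillna("").astype(str)
    out = []
    for (soil, treatment, replicate), grp in df.groupby(
        ["soil", "treatment", "replicate"], sort=True
    ):
        grp = grp.sort_values("day")
        out.append(
            ChemTimeSeries(
                soil=soil,
                treatment=treatment,
                replicate=str(replicate),
                days=tuple(grp["day"].astype(float)),
                nh4=tuple(grp["nh4_mg_kg"].astype(float)),
                no3=tuple(grp["no3_mg_kg"].astype(float)),
            )
        )
    return out


def read_soil_metadata(path: str | Path) -> list[SoilMetadata]:
    """Read a soil-properties TSV (one row per soil, Table-1-style columns)."""
    df = pd.read_csv(path, sep="\t")
    required = {"soil", "ph", "tc_g_kg", "tn_g_kg", "nh4_mg_kg", "no3_mg_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SoilMetadata(
                soil=row["soil"],
                ph=float(row["ph"]),
                tc=float(row["tc_g_kg"]),
                tn=float(row["tn_g_kg"]),
                nh4=float(row["nh4_mg_kg"]),
                no3=float(row["no3_mg_kg"]),
                ap=float(row.get("ap_mg_kg", float("nan"))),
                ak=float(row.get("ak_mg_kg", float("nan"))),
                doc=float(row.get("doc_mg_kg", float("nan"))),
                clay=float(row.get("clay_pct", float("nan"))),
                silt=float(row.get("silt_pct", float("nan"))),
                sand=float(row.get("sand_pct", float("nan"))),
            )
        )
    return out


def write_labeling_table(
    estimates: Iterable[LabelingEstimate], path: str | Path
) -> None:
    rows = []
    for e in estimates:
        rows.append(
            {
                "soil": e.soil,
                "gene": e.gene,
                "replicate": e.replicate,
                "hf_fractions": ",".join(str(i) for i in sorted(e.hf_set)),
                "hf_ratio": e.hf_ratio,
                "total_abundance": e.total_abundance,
                "labeled_abundance": e.labeled_abundance,
                "peak_bd": e.peak_bd,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_zotu_table(
    counts_path: str | Path,
    metadata_path: str | Path,
    taxonomy_path: str | Path,
    fasta_path: str | Path | None = None,
) -> ZotuTable:
    """Assemble a :class:`ZotuTable` from counts, metadata and taxonomy TSVs.

    Counts: rows are Zotus (first column ``zotu``), remaining columns are
    samples. Metadata: one row per sample (first column ``sample``).
    Taxonomy: one row per Zotu with at least a ``clade`` column. An optional
    FASTA of representative sequences is validated for id agreement only.
    """
    counts = pd.read_csv(counts_path, sep="\t").set_index("zotu")
    metadata = pd.read_csv(metadata_path, sep="\t").set_index("sample")
    taxonomy = pd.read_csv(taxonomy_path, sep="\t").set_index("zotu")
    if "clade" not in taxonomy.columns:
        raise ValueError(f"{taxonomy_path}: taxonomy needs a 'clade' column")
    if fasta_path is not None:
        from Bio import SeqIO

        fasta_ids = {rec.id for rec in SeqIO.parse(str(fasta_path), "fasta")}
        missing = set(counts.index) - fasta_ids
        if missing:
            raise ValueError(
                f"{fasta_path}: no representative sequence for {sorted(missing)[:5]}"
            )
    return ZotuTable(counts=counts, metadata=metadata, taxonomy=taxonomy)
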