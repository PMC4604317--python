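"""TSV / VCF input-output for cohort tables and dosage matrices.

One canonical TSV dialect is used throughout: tab-separated, UTF-8, '.'
decimal, 'NA' for missing. Urate is stored in mmol/L; a leading comment
line ``#units: urate=mg/dL`` in a phenotype file declares mg/dL input,
converted on read with the factor 0.05948 mmol/L per mg/dL.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MGDL_TO_MMOLL",
    "read_phenotypes",
    "write_phenotypes",
    "read_dosages",
    "write_dosages_tsv",
    "write_dosages_vcf",
]

MGDL_TO_MMOLL = 0.05948

MANDATORY_COLUMNS = ("id", "cohort", "sex", "age", "bmi", "menopause",
                     "urate", "pc1", "pc2", "flags")
_NUMERIC = ("age", "bmi", "urate", "pc1", "pc2")


def _parse_unit_header(path: str) -> dict[str, str]:
    units: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.lower().startswith("#units:"):
                for part in line.split(":", 1)[1].split(","):
                    if "=" in part:
                        col, unit = part.split("=", 1)
                        units[col.strip()] = unit.strip()
    return units


def read_phenotypes(path: str) -> pd.DataFrame:
    """Read a phenotype TSV into a typed cohort table.

    Mandatory columns: id, cohort, sex, age, bmi, menopause, urate, pc1,
    pc2, flags. Unknown columns are preserved. Raises ``ValueError`` naming
    a missing column, or citing the first offending row for non-numeric
    urate.
    """
    units = _parse_unit_header(path)
    table = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"],
                        keep_default_na=False, dtype={"flags": str})
    for col in MANDATORY_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"missing column: {col}")
    for col in _NUMERIC:
        parsed = pd.to_numeric(table[col], errors="coerce")
        bad = parsed.isna() & table[col].notna() & (table[col].astype(str) != "")
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
            raise ValueError(f"non-numeric {col} at row {row}")
        table[col] = parsed
    if units.get("urate", "mmol/L").lower() in ("mg/dl", "mg_dl", "mgdl"):
        table["urate"] = table["urate"] * MGDL_TO_MMOLL
    table["flags"] = table["flags"].fillna("")
    if "menopause" in table:
        table["menopause"] = table["menopause"].fillna("NA")
    if table["id"].duplicated().any():
        dup = table.loc[table["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate individual id: {dup}")
    if "group" not in table.columns:
        table["group"] = np.where(
            table["sex"] == "male", "men",
            np.where(table["menopause"] == "post", "post", "pre"),
        )
    return table


def write_phenotypes(table: pd.DataFrame, path: str) -> None:
    """Write a cohort table in the canonical TSV dialect (urate in mmol/L)."""
    out = table.copy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_dosages_tsv(matrix: pd.DataFrame, path: str) -> None:
    """Write a dosage matrix (rows = individuals, columns = variants); the
    individual id is the first column."""
    out = matrix.copy()
    out.insert(0, "id", matrix.index)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_dosages_vcf(
    matrix: pd.DataFrame,
    path: str,
    chrom: str = "4",
    start: int = 9_500_000,
    spacing: int = 1_000,
    ref: str = "G",
    alt: str = "T",
) -> None:
    """Write a dosage matrix as an uncompressed VCF with a FORMAT DS field.

    One record per variant at ``start + j * spacing``; the ALT allele is the
    effect allele (dosages are stored unchanged in DS).
    """
    samples = list(matrix.index)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated effect-allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, name in enumerate(matrix.columns):
            ds = "\t".join(f"{v:.3f}" for v in matrix[name].to_numpy(dtype=float))
            fh.write(f"{chrom}\t{start + j * spacing}\t{name}\t{ref}\t{alt}\t.\t.\t.\tDS\t{ds}\n")


def _read_dosages_vcf(path: str, effect_alleles: Mapping[str, str] | None) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    positions: dict[str, int] = {}
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        ds = variant.format("DS")
        if ds is None:
            raise ValueError(f"variant {vid} has no DS format field")
        dosage = np.asarray(ds, dtype=float).reshape(-1)
        effect = None if effect_alleles is None else effect_alleles.get(vid)
        if effect is not None and effect == variant.REF:
            dosage = 2.0 - dosage
        if np.any((dosage < 0) | (dosage > 2)):
            raise ValueError(f"dosage outside [0, 2] for variant {vid}")
        columns[vid] = dosage
        positions[vid] = variant.POS
    matrix = pd.DataFrame(columns, index=samples)
    matrix.attrs["positions"] = positions
    return matrix


def _read_dosages_tsv(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "id" not in table.columns:
        raise ValueError("missing column: id")
    matrix = table.set_index("id")
    values = matrix.to_numpy(dtype=float)
    if np.any((values < 0) | (values > 2)):
        raise ValueError("dosage outside [0, 2] in dosage TSV")
    return matrix


def read_dosages(
    path: str,
    format: str | None = None,
    sample_ids: Sequence[str] | None = None,
    effect_alleles: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a dosage matrix (individuals × variants) from VCF or TSV.

    ``format`` is inferred from the extension when omitted. For VCF the ALT
    allele is the effect allele unless ``effect_alleles`` maps a variant id
    to its effect allele; mapping to REF flips dosages to 2 - DS. When
    ``sample_ids`` is given the matrix is aligned to those individuals;
    samples absent from the file are an error if nothing overlaps.
    """
    if format is None:
        format = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if format not in ("vcf", "tsv"):
        raise ValueError(f"unknown dosage format: {format!r}")
    matrix = _read_dosages_vcf(path, effect_alleles) if format == "vcf" else _read_dosages_tsv(path)
    if sample_ids is not None:
        sample_ids = list(sample_ids)
        overlap = [s for s in sample_ids if s in matrix.index]
        if not overlap:
            raise ValueError("no overlapping samples between phenotypes and dosages")
        missing = [s for s in sample_ids if s not in matrix.index]
        if missing:
            raise ValueError(
                f"{len(missing)} phenotype samples missing from dosage file "
                f"(first: {missing[0]})"
            )
        matrix = matrix.loc[sample_ids]
    return matrix
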