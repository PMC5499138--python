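"""Readers and writers for on-disk artifacts.

Formats: a minimal VCF v4.2 subset (CHROM, POS, ID, REF, ALT and either a
GT field for integer dosages or a DS field for real-valued family-bulk
dosages), a HapMap-like numeric TSV (marker, chrom, pos, one column per
sample), a map TSV, a phenotype CSV, and labeled square TSVs for
relationship matrices. Readers always return markers sorted by
(chromosome, bp position); writers and readers round-trip dosages exactly.

GT-based VCFs are parsed with cyvcf2. The DS dialect is parsed here:
htslib-backed readers return FORMAT floats as 32-bit, which would break
the exact round-trip of float64 bulk dosages.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome import GeneticMap, GenotypeTable

logger = logging.getLogger(__name__)

PHENO_REQUIRED = ["entry", "cycle", "location", "replicate"]
TRAITS = ["GY", "AD", "SD", "PH", "EH", "MOI"]


class ParseError(ValueError):
    """Malformed record in an input file; the message names the line."""


# ---------------------------------------------------------------------------
# genetic map


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    missing = [c for c in ("marker", "chrom", "pos_bp", "pos_cM") if c not in df.columns]
    if missing:
        raise ParseError(f"map file {path} missing columns {missing}")
    return GeneticMap(df)


def write_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF dialect


def _vcf_header(samples, fractional: bool, contigs=()) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=rcgs"]
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    lines.append('##INFO=<ID=CM,Number=1,Type=String,Description="Genetic position (cM)">')
    if fractional:
        lines.append('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Reference-allele dosage">')
    else:
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"] + list(samples)
    lines.append("\t".join(cols))
    return "\n".join(lines)


def write_vcf(table: GenotypeTable, path) -> None:
    """Write the minimal VCF dialect.

    Integer-valued tables are written with GT calls; any fractional dosage
    switches the whole file to the DS field so family bulks stay lossless.
    Missing cells become ``./.`` or ``.``.
    """
    dos = table.dosage
    finite = dos[~np.isnan(dos)]
    fractional = bool(np.any(finite != np.round(finite)))
    gmap = table.map
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write(_vcf_header(table.samples, fractional, gmap.chromosomes()) + "\n")
        if table.n_samples == 0:
            return
        for j in range(gmap.n_markers):
            fixed = [
                str(gmap.chrom[j]),
                str(int(gmap.pos_bp[j])),
                str(gmap.markers[j]),
                "A",
                "T",
                ".",
                "PASS",
                f"CM={float(gmap.pos_cM[j])!r}",
                "DS" if fractional else "GT",
            ]
            if fractional:
                calls = [
                    "." if np.isnan(x) else repr(float(x)) for x in dos[:, j]
                ]
            else:
                calls = ["./." if np.isnan(x) else gt_code[float(x)] for x in dos[:, j]]
            fh.write("\t".join(fixed + calls) + "\n")


def _read_vcf_ds(path) -> GenotypeTable:
    """Parse the DS (fractional dosage) dialect written by :func:`write_vcf`."""
    samples: list = []
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            if len(parts) != 9 + len(samples):
                raise ParseError(f"{path}:{lineno}: expected {9 + len(samples)} fields, got {len(parts)}")
            chrom, pos, mid, _ref, _alt, _qual, _filt, info, fmt = parts[:9]
            if fmt != "DS":
                raise ParseError(f"{path}:{lineno}: expected DS format, got {fmt!r}")
            cm = 0.0
            for kv in info.split(";"):
                if kv.startswith("CM="):
                    cm = float(kv[3:])
            try:
                calls = [np.nan if c == "." else float(c) for c in parts[9:]]
                rows.append((mid, chrom, int(pos), cm, calls))
            except ValueError as err:
                raise ParseError(f"{path}:{lineno}: {err}") from None
    return _assemble(samples, rows)


def _assemble(samples, rows) -> GenotypeTable:
    if not rows:
        raise ParseError("no variant records found")
    map_df = pd.DataFrame(
        [(r[0], r[1], r[2], r[3]) for r in rows],
        columns=["marker", "chrom", "pos_bp", "pos_cM"],
    )
    dosage = np.array([r[4] for r in rows], dtype=float).T
    order = map_df.sort_values(["chrom", "pos_bp"], kind="mergesort").index.to_numpy()
    if not np.array_equal(order, np.arange(len(rows))):
        logger.warning("input markers not sorted by (chrom, pos); sorting")
    gmap = GeneticMap(map_df.iloc[order].reset_index(drop=True))
    return GenotypeTable(list(samples), gmap, dosage[:, order] if dosage.size else dosage)


def _read_vcf_gt(path) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    code = {0: 0.0, 1: 1.0, 2: np.nan, 3: 2.0}  # cyvcf2 gt_types
    for v in vcf:
        cm = 0.0
        raw = v.INFO.get("CM")
        if raw is not None:
            cm = float(raw)
        calls = [code[int(t)] for t in v.gt_types]
        rows.append((v.ID or f"{v.CHROM}_{v.POS}", v.CHROM, v.POS, cm, calls))
    return _assemble(samples, rows)


def read_vcf(path) -> GenotypeTable:
    """Read the minimal VCF dialect (GT or DS based)."""
    with open(path) as fh:
        head = fh.read(8192)
    if "ID=DS" in head:
        return _read_vcf_ds(path)
    return _read_vcf_gt(path)


# ---------------------------------------------------------------------------
# HapMap-like TSV


def write_hapmap(table: GenotypeTable, path) -> None:
    gmap = table.map
    df = pd.DataFrame(
        {
            "marker": gmap.markers,
            "chrom": gmap.chrom,
            "pos_bp": gmap.pos_bp,
            "pos_cM": gmap.pos_cM,
        }
    )
    for i, s in enumerate(table.samples):
        df[s] = table.dosage[i]
    df.to_csv(path, sep="\t", index=False, float_format=None, na_rep="NA")


def read_hapmap(path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"], float_precision="round_trip")
    fixed = ["marker", "chrom", "pos_bp", "pos_cM"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ParseError(f"hapmap file {path} missing columns {missing}")
    samples = [c for c in df.columns if c not in fixed]
    rows = [
        (r.marker, r.chrom, int(r.pos_bp), float(r.pos_cM), [getattr(r, s) for s in samples])
        for r in df.itertuples()
    ]
    return _assemble(samples, rows)


def read_genotypes(path, format: str) -> GenotypeTable:
    """Dispatch to the named dialect ({'vcf', 'hapmap_tsv'})."""
    if format == "vcf":
        return read_vcf(path)
    if format == "hapmap_tsv":
        return read_hapmap(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(table: GenotypeTable, path, format: str) -> None:
    if format == "vcf":
        write_vcf(table, path)
    elif format == "hapmap_tsv":
        write_hapmap(table, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# phenotypes and reports


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype CSV -> typed records; validates the unique plot key."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PHENO_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"phenotype file {path} missing columns {missing}")
    if "is_check" not in df.columns:
        df["is_check"] = df["cycle"].astype(str).str.lower().eq("check")
    if "family" not in df.columns:
        df["family"] = df["entry"]
    if "block" not in df.columns:
        df["block"] = 1
    key = ["entry", "location", "replicate"]
    if df.duplicated(key).any():
        dup = df[df.duplicated(key, keep=False)].iloc[0]
        raise ParseError(
            f"duplicate plot record for entry={dup['entry']!r} "
            f"location={dup['location']!r} replicate={dup['replicate']!r}"
        )
    if "GY" in df.columns and (df["GY"].dropna() < 0).any():
        raise ParseError("negative grain yield in phenotype file")
    return df


def write_phenotypes(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def write_report(table: pd.DataFrame, path) -> None:
    """Write any tidy report table as TSV."""
    table.to_csv(path, sep="\t", index=False)


def write_grm(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=True, index_label="sample")


def read_grm(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")
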