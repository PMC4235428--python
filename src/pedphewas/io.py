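"""Readers and writers for the formats the pipeline touches.

PLINK bed/bim/fam (variant-major, hard calls), VCF (GT hard calls or DS
dosages, read through cyvcf2; written as plain uncompressed text), and
the CSV/TSV tables (events, sites, phecode map, association results).
Genomic positions are 1-based throughout.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError, StructuralError
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # variant-major bed
# 2-bit codes -> dosage of A1: 00 hom-A1, 01 missing, 10 het, 11 hom-A2
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


# ---------------------------------------------------------------------------
# PLINK bed / bim / fam
# ---------------------------------------------------------------------------

def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write hard-call genotypes as PLINK bed/bim/fam.

    Fractional dosages cannot be represented; use :func:`write_vcf`.
    """
    prefix = Path(prefix)
    d = G.dosages
    finite = d[~np.isnan(d)]
    if finite.size and not np.array_equal(finite, np.round(finite)):
        raise ParameterError("bed holds hard calls only; write dosages to VCF")
    n = G.n_subjects
    n_bytes = (n + 3) // 4
    # dosage -> 2-bit code
    codes = np.full(d.shape, 1, dtype=np.uint8)       # missing
    codes[d == 2.0] = 0
    codes[d == 1.0] = 2
    codes[d == 0.0] = 3
    padded = np.zeros((n_bytes * 4, G.n_variants), dtype=np.uint8)
    padded[:n] = codes
    packed = np.zeros((n_bytes, G.n_variants), dtype=np.uint8)
    for off in range(4):
        packed |= padded[off::4] << np.uint8(2 * off)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.T.tobytes())  # variant-major
    bim = pd.DataFrame(
        {
            "chrom": G.variants["chrom"],
            "id": G.variants["id"],
            "cm": 0,
            "pos": G.variants["pos"],
            "a1": G.variants["a1"],
            "a2": G.variants["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": G.subjects,
            "iid": G.subjects,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam fileset into a GenotypeMatrix."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"id": str, "a1": str, "a2": str},
    )
    if fam.empty or bim.empty:
        raise StructuralError("empty fam or bim file")
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise StructuralError(
            "bad bed magic bytes (expected variant-major 0x6c1b01)"
        )
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != m * n_bytes:
        raise StructuralError(
            f"bed payload is {body.size} bytes but bim lists {m} variants "
            f"x fam {n} subjects => expected {m * n_bytes}"
        )
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    for off in range(4):
        codes[:, off::4] = (body >> (2 * off)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T
    variants = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    variants["pos"] = variants["pos"].astype(int)
    return GenotypeMatrix(
        subjects=fam["iid"].to_numpy(dtype=object),
        variants=variants,
        dosages=dosages,
        hard_calls=True,
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as an uncompressed VCF with GT and DS fields.

    DS carries the A1 (ALT) dosage to 4 decimals; GT is the rounded hard
    call (./. where the rounding tolerance is exceeded or data missing).
    """
    path = Path(path)
    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">\n')
        for chrom in pd.unique(G.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, G.subjects)) + "\n")
        for j in range(G.n_variants):
            v = G.variants.iloc[j]
            fields = [str(v["chrom"]), str(v["pos"]), str(v["id"]),
                      str(v["a2"]), str(v["a1"]), ".", "PASS", ".", "GT:DS"]
            for d in G.dosages[:, j]:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    rounded = float(np.round(d))
                    gt = gt_codes[rounded] if abs(d - rounded) <= 0.1 else "./."
                    fields.append(f"{gt}:{d:.4f}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (requires cyvcf2).

    The counted A1 allele is ALT. When a DS FORMAT field is present it
    overrides GT (documented precedence: imputed dosages win over the
    hard calls they were derived from). Multi-allelic records are
    skipped with a warning.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    subjects = np.array(vcf.samples, dtype=object)
    rows, meta = [], []
    for record in vcf:
        if len(record.ALT) != 1:
            logger.warning("skipping multi-allelic record %s", record.ID)
            continue
        ds = None
        try:
            ds = record.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = ds[:, 0].astype(float)
            dose[~np.isfinite(dose)] = np.nan
        else:
            gts = np.array(record.genotypes, dtype=object)
            dose = np.array(
                [np.nan if g[0] < 0 or g[1] < 0 else float(g[0] + g[1]) for g in gts]
            )
        rows.append(dose)
        meta.append((record.ID or f"{record.CHROM}:{record.POS}",
                     record.CHROM, record.POS, record.ALT[0], record.REF))
    if not meta:
        raise StructuralError("VCF contains no usable biallelic records")
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos", "a1", "a2"])
    dosages = np.column_stack(rows)
    finite = dosages[~np.isnan(dosages)]
    hard = bool(finite.size == 0 or np.array_equal(finite, np.round(finite)))
    return GenotypeMatrix(subjects, variants, dosages, hard_calls=hard)


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Dispatch on format: ``plink`` (prefix of a bed/bim/fam trio) or
    ``vcf``. Guessed from the filename when ``fmt`` is omitted."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz") else "plink"
    if fmt == "plink":
        return read_plink(path.with_suffix("") if path.suffix == ".bed" else path)
    if fmt == "vcf":
        return read_vcf(path)
    raise ParameterError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_events(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path, dtype={"subject_id": str, "icd9": str})
    if not {"subject_id", "icd9"} <= set(events.columns):
        raise StructuralError("events CSV needs subject_id and icd9 columns")
    return events


def read_sites(path: str | Path) -> pd.DataFrame:
    sites = pd.read_csv(path, dtype=str)
    if not {"subject_id", "site"} <= set(sites.columns):
        raise StructuralError("sites CSV needs subject_id and site columns")
    return sites


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """TSV with fixed column order, NA for missing, and 3-significant-
    digit scientific notation for p/q columns."""
    out = frame.copy()
    for col in out.columns:
        if col in ("p", "q", "p_perm", "hwe_p", "site_diff_p"):
            out[col] = out[col].map(
                lambda v: "NA" if pd.isna(v) else f"{v:.3g}"
            )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
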