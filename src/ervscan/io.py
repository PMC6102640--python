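"""Readers and writers for the plain-text formats the pipeline consumes.

Conventions
-----------
* BED and all internal coordinates are 0-based half-open.
* VCF coordinates are 1-based at the file boundary only.
* Genotype dosage is the ALT allele count in {0, 1, 2}; missing is -1.
* Chromosome naming must be consistent across every input of a run;
  :func:`check_chrom_consistency` raises on a chr1/1 style mix.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

from ._seq import decode, encode
from .errors import InputError

# ---------------------------------------------------------------- FASTA/FASTQ


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            out[rec.name] = rec.sequence.upper()
    if not out:
        raise InputError(f"no FASTA records in {path}")
    return out


def read_fasta_encoded(path: str | Path) -> dict[str, np.ndarray]:
    return {name: encode(seq) for name, seq in read_fasta(path).items()}


def write_fasta(path: str | Path, records: dict[str, str | np.ndarray], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            if isinstance(seq, np.ndarray):
                seq = decode(seq)
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.name, rec.sequence.upper(), rec.quality or ""


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ------------------------------------------------------------------------ BED

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED_COLUMNS[:3]).astype({"start": int, "end": int})
    df.columns = BED_COLUMNS[: df.shape[1]] + list(df.columns[6:])
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df.index[df["end"] < df["start"]]
    if len(bad):
        raise InputError(f"{path}: interval end < start at line {bad[0] + 1}")
    return df


def write_bed(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


# ------------------------------------------------------------------------ VCF


def read_vcf_genotypes(path: str | Path):
    """Biallelic SNP records from a VCF.

    Returns ``(samples, records)`` where records is a DataFrame with one
    row per biallelic SNP (id, chrom, pos [0-based], ref, alt) and a
    ``dosage`` matrix attribute (n_snps x n_samples, int8, -1 missing).
    Non-SNP and multi-allelic records are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS - 1)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        gt = var.gt_types.astype(np.int8)  # 0,1,2 and 3 = unknown
        gt[gt == 3] = -1
        rows.append(gt)
    vcf.close()
    df = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    dosage = np.vstack(rows).astype(np.int8) if rows else np.empty((0, len(samples)), np.int8)
    return samples, df, dosage


def write_vcf_genotypes(
    path: str | Path,
    samples: list[str],
    records: pd.DataFrame,
    dosage: np.ndarray,
    contigs: dict[str, int] | None = None,
) -> None:
    """Minimal VCF 4.2 writer for biallelic SNP genotypes (unphased GT)."""
    gt_str = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for i, rec in enumerate(records.itertuples()):
            gts = "\t".join(gt_str[int(d)] for d in dosage[i])
            fh.write(f"{rec.chrom}\t{rec.pos + 1}\t{rec.id}\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_sv_deletions(path: str | Path) -> pd.DataFrame:
    """Deletion intervals (chrom, start, end, length) from an SV VCF.

    VCF places POS on the padding base before the event, so the deleted
    bases are [POS, END) in 0-based half-open terms.  Length comes from
    SVLEN when present, else END - POS.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    rows = []
    for var in vcf:
        svtype = var.INFO.get("SVTYPE")
        if svtype is not None and svtype != "DEL":
            continue
        if svtype is None and not (var.ALT and var.ALT[0] == "<DEL>"):
            continue
        start = var.POS  # first deleted base, 0-based
        svlen = var.INFO.get("SVLEN")
        end = var.INFO.get("END")
        if svlen is not None:
            length = abs(int(svlen[0] if isinstance(svlen, (tuple, list)) else svlen))
            end = start + length
        elif end is not None:
            end = int(end)
            length = end - start
        else:
            continue
        rows.append((var.CHROM, start, int(end), int(length)))
    vcf.close()
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "length"])


def write_sv_vcf(path: str | Path, deletions: pd.DataFrame, contigs: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, rec in enumerate(deletions.itertuples()):
            # POS sits on the padding base preceding the deleted interval
            info = f"SVTYPE=DEL;END={rec.end};SVLEN=-{rec.length}"
            fh.write(f"{rec.chrom}\t{rec.start}\tdel{i}\tN\t<DEL>\t.\tPASS\t{info}\n")


# -------------------------------------------------------------------- tables


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_presence_matrix(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index), list(df.columns), df.to_numpy(dtype=np.int8)


def write_presence_matrix(
    path: str | Path, site_ids: list[str], individual_ids: list[str], calls: np.ndarray
) -> None:
    pd.DataFrame(calls, index=site_ids, columns=individual_ids).to_csv(
        path, sep="\t", index_label="site_id"
    )


# ------------------------------------------------------------------ checking


def check_chrom_consistency(named_sets: dict[str, set[str]]) -> None:
    """Raise if inputs mix chromosome-naming styles (e.g. 'chr1' vs '1')."""
    styles = {name: {c.startswith("chr") for c in chroms if c}
              for name, chroms in named_sets.items() if chroms}
    flat = set().union(*styles.values()) if styles else set()
    if len(flat) > 1:
        offenders = ", ".join(
            f"{name} ({'chr-prefixed' if True in st else 'bare'})"
            for name, st in styles.items()
        )
        raise InputError(f"inconsistent chromosome naming across inputs: {offenders}")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
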