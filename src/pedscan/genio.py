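"""Genotype file I/O: VCF and whitespace marker-matrix formats.

Two input forms are accepted: a VCF of biallelic SNVs (GT field, missing
"./.") read through cyvcf2, and a plain marker-by-individual dosage matrix
accompanied by a 4-column map file (marker, chromosome, bp, minor allele).
Multiallelic VCF records are skipped or rejected per ``multiallelic``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

from .ibd import IbdError, MarkerGenotypes

logger = logging.getLogger(__name__)

MISSING_CODE = "NA"


def read_genotypes_vcf(
    path: str | Path, multiallelic: str = "skip"
) -> list[MarkerGenotypes]:
    """Read biallelic SNVs from a VCF into dosage records.

    Dosage counts the ALT allele (relabelled later if ALT turns out to be
    the major allele; see ``estimate_allele_freq``).  ``multiallelic`` is
    "skip" (drop with a warning) or "error".
    """
    from cyvcf2 import VCF

    if multiallelic not in ("skip", "error"):
        raise ValueError(f"multiallelic must be 'skip' or 'error', got {multiallelic!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: list[MarkerGenotypes] = []
    for var in vcf:
        if len(var.ALT) != 1:
            if multiallelic == "error":
                raise IbdError(
                    f"multiallelic record at {var.CHROM}:{var.POS} "
                    f"({var.REF}->{var.ALT})"
                )
            logger.warning(
                "skipping multiallelic record at %s:%s", var.CHROM, var.POS
            )
            continue
        # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        dosage_map = {0: 0, 1: 1, 3: 2, 2: None}
        dosages = {
            s: dosage_map[int(t)] for s, t in zip(samples, var.gt_types)
        }
        mid = var.ID or f"{var.CHROM}:{var.POS}"
        out.append(MarkerGenotypes(mid, str(var.CHROM), int(var.POS), dosages))
    return out


def write_genotypes_vcf(
    markers: Sequence[MarkerGenotypes], ids: Sequence[str], path: str | Path
) -> None:
    """Write dosages as a minimal uncompressed VCF (GT only, A/B alleles)."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({m.chromosome for m in markers})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ids)
            + "\n"
        )
        for m in sorted(markers, key=lambda m: (m.chromosome, m.position_bp)):
            calls = "\t".join(gt[m.dosage(i)] for i in ids)
            fh.write(
                f"{m.chromosome}\t{m.position_bp}\t{m.marker_id}\tA\tB\t.\t.\t.\tGT\t{calls}\n"
            )


def read_marker_matrix(
    geno_path: str | Path, map_path: str | Path
) -> list[MarkerGenotypes]:
    """Read a whitespace dosage matrix plus its 4-column map file.

    Matrix: header line ``marker id1 id2 ...`` then one row per marker with
    dosages 0/1/2 or ``NA``.  Map: marker, chromosome, bp, minor allele.
    """
    mapping: dict[str, tuple[str, int]] = {}
    with Path(map_path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 4:
                raise IbdError(f"{map_path}:{lineno}: expected 4 columns")
            mapping[fields[0]] = (fields[1], int(fields[2]))
    out = []
    with Path(geno_path).open() as fh:
        header = fh.readline().split()
        if not header or header[0] != "marker":
            raise IbdError(f"{geno_path}: first line must start with 'marker'")
        ids = header[1:]
        for lineno, line in enumerate(fh, 2):
            fields = line.split()
            if not fields:
                continue
            mid = fields[0]
            if mid not in mapping:
                raise IbdError(f"{geno_path}:{lineno}: marker {mid!r} not in map")
            if len(fields) != len(ids) + 1:
                raise IbdError(
                    f"{geno_path}:{lineno}: expected {len(ids)} dosages"
                )
            dosages = {
                i: (None if v == MISSING_CODE else int(v))
                for i, v in zip(ids, fields[1:])
            }
            chrom, pos = mapping[mid]
            out.append(MarkerGenotypes(mid, chrom, pos, dosages))
    return out


def write_marker_matrix(
    markers: Sequence[MarkerGenotypes],
    ids: Sequence[str],
    geno_path: str | Path,
    map_path: str | Path,
) -> None:
    with Path(geno_path).open("w") as fh:
        fh.write("marker " + " ".join(ids) + "\n")
        for m in markers:
            row = " ".join(
                MISSING_CODE if m.dosage(i) is None else str(m.dosage(i))
                for i in ids
            )
            fh.write(f"{m.marker_id} {row}\n")
    with Path(map_path).open("w") as fh:
        for m in markers:
            fh.write(f"{m.marker_id}\t{m.chromosome}\t{m.position_bp}\tB\n")


def read_genotypes(
    path: str | Path, map_path: str | Path | None = None
) -> list[MarkerGenotypes]:
    """Dispatch on extension: .vcf -> VCF reader, else marker matrix (+map)."""
    p = Path(path)
    if p.suffix == ".vcf" or p.name.endswith(".vcf.gz"):
        return read_genotypes_vcf(p)
    if map_path is None:
        raise IbdError("marker-matrix input requires a map file")
    return read_marker_matrix(p, map_path)
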