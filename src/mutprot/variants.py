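"""Somatic-variant model and the four-clause somatic filter.

A variant passes iff tumor_alt_reads > 3 AND normal_alt_reads < 3 AND
tumor VAF > 0.05 AND it is not in a simple repeat. All four comparisons
are strict; boundary values (3, 3, 0.05) fail.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

#: default strict thresholds, overridable per call
TUMOR_ALT_MIN_EXCL = 3
NORMAL_ALT_MAX_EXCL = 3
VAF_MIN_EXCL = 0.05

TSV_COLUMNS = [
    "accession", "gene", "type", "cds_pos", "protein_pos",
    "ref_aa", "alt_aa", "ref_base", "alt_base",
    "tumor_alt", "tumor_depth", "normal_alt", "normal_depth", "simple_repeat",
]


class VariantFormatError(ValueError):
    """Malformed variant table (missing column, bad row)."""


class VariantValidationError(ValueError):
    """Record violates a VariantCall invariant."""


@dataclass(frozen=True)
class VariantCall:
    accession: str
    gene: str
    type: str  # "missense" | "frameshift"
    cds_pos: int
    protein_pos: int
    ref_aa: str | None
    alt_aa: str | None
    ref_base: str
    alt_base: str
    tumor_alt_reads: int
    tumor_total_reads: int
    normal_alt_reads: int
    normal_total_reads: int
    simple_repeat: bool

    def __post_init__(self) -> None:
        if self.type not in ("missense", "frameshift"):
            raise VariantValidationError(f"unknown variant type {self.type!r}")
        if self.tumor_alt_reads > self.tumor_total_reads:
            raise VariantValidationError(
                f"{self.key}: tumor_alt {self.tumor_alt_reads} > depth {self.tumor_total_reads}"
            )
        if self.normal_alt_reads > self.normal_total_reads:
            raise VariantValidationError(
                f"{self.key}: normal_alt {self.normal_alt_reads} > depth {self.normal_total_reads}"
            )
        if min(self.tumor_alt_reads, self.tumor_total_reads,
               self.normal_alt_reads, self.normal_total_reads) < 0:
            raise VariantValidationError(f"{self.key}: negative read count")
        if self.protein_pos < 1:
            raise VariantValidationError(f"{self.key}: protein_pos must be >= 1")
        if self.type == "missense" and self.ref_aa == self.alt_aa:
            raise VariantValidationError(f"{self.key}: synonymous (ref_aa == alt_aa)")

    @property
    def key(self) -> str:
        return f"{self.accession}:{self.hgvs_p}"

    @property
    def hgvs_p(self) -> str:
        if self.type == "missense":
            return f"p.{self.ref_aa}{self.protein_pos}{self.alt_aa}"
        return f"p.X{self.protein_pos}fs"


@dataclass(frozen=True)
class FilterResult:
    variant: VariantCall
    passed: bool
    vaf_tumor: float
    failed_clauses: frozenset[str]
    zero_depth: bool = False


def apply_somatic_filters(
    variants: list[VariantCall],
    tumor_alt_min: int = TUMOR_ALT_MIN_EXCL,
    normal_alt_max: int = NORMAL_ALT_MAX_EXCL,
    vaf_min: float = VAF_MIN_EXCL,
) -> list[FilterResult]:
    """Evaluate the four somatic criteria on each variant, order preserved."""
    results = []
    for v in variants:
        failed = set()
        zero_depth = v.tumor_total_reads == 0
        vaf = 0.0 if zero_depth else v.tumor_alt_reads / v.tumor_total_reads
        if not v.tumor_alt_reads > tumor_alt_min:
            failed.add("i")
        if not v.normal_alt_reads < normal_alt_max:
            failed.add("ii")
        if not vaf > vaf_min:
            failed.add("iii")
        if v.simple_repeat:
            failed.add("iv")
        results.append(
            FilterResult(
                variant=v,
                passed=not failed,
                vaf_tumor=vaf,
                failed_clauses=frozenset(failed),
                zero_depth=zero_depth,
            )
        )
    return results


def _parse_row(row: dict[str, str], line_no: int) -> VariantCall:
    def opt(key: str) -> str | None:
        val = row.get(key, "").strip()
        return val or None

    try:
        return VariantCall(
            accession=row["accession"],
            gene=row["gene"],
            type=row["type"],
            cds_pos=int(row["cds_pos"]),
            protein_pos=int(row["protein_pos"]),
            ref_aa=opt("ref_aa"),
            alt_aa=opt("alt_aa"),
            ref_base=row["ref_base"],
            alt_base=row["alt_base"],
            tumor_alt_reads=int(row["tumor_alt"]),
            tumor_total_reads=int(row["tumor_depth"]),
            normal_alt_reads=int(row["normal_alt"]),
            normal_total_reads=int(row["normal_depth"]),
            simple_repeat=row["simple_repeat"].strip().lower() in ("1", "true", "yes"),
        )
    except VariantValidationError as exc:
        raise VariantValidationError(f"line {line_no}: {exc}") from exc
    except (KeyError, ValueError) as exc:
        raise VariantFormatError(f"line {line_no}: malformed row ({exc})") from exc


def read_variant_table(path: str | Path, dialect: str = "tsv") -> list[VariantCall]:
    """Read a variant table in the TSV dialect or the minimal-VCF dialect."""
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "vcf-min":
        return _read_vcf_min(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'vcf-min')")


def _read_tsv(path: Path) -> list[VariantCall]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = set(TSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise VariantFormatError(f"missing mandatory column(s): {sorted(missing)}")
        return [_parse_row(row, i) for i, row in enumerate(reader, start=2)]


def write_variant_table(variants: list[VariantCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for v in variants:
            writer.writerow([
                v.accession, v.gene, v.type, v.cds_pos, v.protein_pos,
                v.ref_aa or "", v.alt_aa or "", v.ref_base, v.alt_base,
                v.tumor_alt_reads, v.tumor_total_reads,
                v.normal_alt_reads, v.normal_total_reads,
                "true" if v.simple_repeat else "false",
            ])


# --- minimal VCF dialect: AD-style counts in TUMOR/NORMAL sample columns ---

_VCF_INFO_KEYS = ("GENE", "TYPE", "CDS_POS", "PROT_POS", "REF_AA", "ALT_AA", "REPEAT")


def _read_vcf_min(path: Path) -> list[VariantCall]:
    variants = []
    sample_names: list[str] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                sample_names = fields[9:]
                if "TUMOR" not in sample_names or "NORMAL" not in sample_names:
                    raise VariantFormatError(
                        f"line {line_no}: need TUMOR and NORMAL sample columns, got {sample_names}"
                    )
                continue
            if not sample_names:
                raise VariantFormatError("missing #CHROM header line")
            fields = line.split("\t")
            if len(fields) < 9 + len(sample_names):
                raise VariantFormatError(f"line {line_no}: truncated record")
            _chrom, _pos, vid, ref, alt, _qual, _flt, info, fmt = fields[:9]
            info_map = dict(
                kv.split("=", 1) if "=" in kv else (kv, "true")
                for kv in info.split(";") if kv
            )
            missing = [k for k in _VCF_INFO_KEYS[:4] if k not in info_map]
            if missing:
                raise VariantFormatError(f"line {line_no}: missing INFO key(s) {missing}")
            fmt_keys = fmt.split(":")
            if "AD" not in fmt_keys:
                raise VariantFormatError(f"line {line_no}: FORMAT lacks AD")
            ad_idx = fmt_keys.index("AD")
            samples = dict(zip(sample_names, fields[9:]))

            def ad_counts(sample: str) -> tuple[int, int]:
                ref_n, alt_n = samples[sample].split(":")[ad_idx].split(",")[:2]
                return int(alt_n), int(ref_n) + int(alt_n)

            t_alt, t_tot = ad_counts("TUMOR")
            n_alt, n_tot = ad_counts("NORMAL")
            acc = vid.split("|")[0] if vid != "." else info_map.get("ACC", ".")
            variants.append(
                VariantCall(
                    accession=acc,
                    gene=info_map.get("GENE", ""),
                    type=info_map["TYPE"],
                    cds_pos=int(info_map["CDS_POS"]),
                    protein_pos=int(info_map["PROT_POS"]),
                    ref_aa=info_map.get("REF_AA") or None,
                    alt_aa=info_map.get("ALT_AA") or None,
                    ref_base=ref,
                    alt_base=alt,
                    tumor_alt_reads=t_alt,
                    tumor_total_reads=t_tot,
                    normal_alt_reads=n_alt,
                    normal_total_reads=n_tot,
                    simple_repeat=info_map.get("REPEAT", "false").lower() == "true",
                )
            )
    return variants


def write_vcf_min(variants: list[VariantCall], path: str | Path) -> None:
    """Minimal VCF with AD counts in TUMOR/NORMAL columns."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL",
    ]
    for v in variants:
        info = (
            f"GENE={v.gene};TYPE={v.type};CDS_POS={v.cds_pos};PROT_POS={v.protein_pos}"
            + (f";REF_AA={v.ref_aa};ALT_AA={v.alt_aa}" if v.ref_aa else "")
            + (";REPEAT=true" if v.simple_repeat else "")
        )
        t_ref = v.tumor_total_reads - v.tumor_alt_reads
        n_ref = v.normal_total_reads - v.normal_alt_reads
        lines.append(
            "\t".join([
                "1", str(v.cds_pos), v.accession, v.ref_base, v.alt_base, ".", ".",
                info, "AD", f"{t_ref},{v.tumor_alt_reads}", f"{n_ref},{v.normal_alt_reads}",
            ])
        )
    Path(path).write_text("\n".join(lines) + "\n")
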