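"""Variant sites and input parsing (VCF, barcode lists).

Coordinates follow the VCF convention on the way in (1-based ``pos``) and
are converted to 0-based exactly once, at parse time: ``VariantSite.pos``
stores the 1-based VCF position while ``pos0`` gives the 0-based reference
index of the variant base (for indels, of the anchor base).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import pysam

SNV = "snv"
INSERTION = "insertion"
DELETION = "deletion"


@dataclass(frozen=True)
class VariantSite:
    """One somatic variant locus with optional bulk-DNA annotations.

    ``vaf_ewgs`` is the variant allele frequency measured in (enhanced)
    whole-genome sequencing of the same tumor; ``subclone`` labels the
    clone-tree node the variant belongs to ("founding" or a subclone id).
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    var_type: str | None = None
    gene: str | None = None
    vaf_ewgs: float | None = None
    subclone: str | None = None
    expressed: bool | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (got {self.pos})")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        vt = self.var_type
        if vt is None:
            vt = classify_alleles(self.ref, self.alt)
            object.__setattr__(self, "var_type", vt)
        if vt == SNV and not (len(self.ref) == len(self.alt) == 1):
            raise ValueError("snv requires single-base ref and alt")
        if vt in (INSERTION, DELETION) and len(self.ref) == len(self.alt):
            raise ValueError("indel requires ref/alt of different length")
        if vt not in (SNV, INSERTION, DELETION):
            raise ValueError(f"unknown var_type {vt!r}")
        if self.vaf_ewgs is not None and not 0.0 <= self.vaf_ewgs <= 1.0:
            raise ValueError("vaf_ewgs must lie in [0, 1]")

    @property
    def pos0(self) -> int:
        """0-based reference index of the variant (anchor) base."""
        return self.pos - 1

    @property
    def indel_length(self) -> int:
        """Length of inserted/deleted sequence (0 for SNVs)."""
        return abs(len(self.alt) - len(self.ref))

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def from_key(cls, key: str, **kwargs) -> "VariantSite":
        chrom, pos, ref, alt = key.rsplit(":", 3)
        return cls(chrom=chrom, pos=int(pos), ref=ref, alt=alt, **kwargs)


def classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return SNV
    if len(alt) > len(ref):
        return INSERTION
    if len(alt) < len(ref):
        return DELETION
    raise ValueError(f"cannot classify {ref}>{alt} (MNVs unsupported)")


def left_normalize(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Trim a shared suffix/prefix from an allele pair (VCF left-normalization).

    Only string-level trimming is done; reference-aware left-shifting of
    repeats would need the reference sequence and is out of scope.
    """
    # trim common suffix, keeping at least one base each
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim common prefix, advancing pos
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def load_variants(vcf_path: str) -> list[VariantSite]:
    """Read somatic variant sites from a VCF 4.x file.

    Recognized INFO keys: ``VAF`` (float), ``SUBCLONE`` (string), ``GENE``
    (string), ``TYPE`` (string, optional; inferred from alleles otherwise).
    Multi-allelic records must have been split upstream.
    """
    sites: list[VariantSite] = []
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            if len(rec.alts) != 1:
                raise ValueError(
                    f"multi-allelic record at {rec.chrom}:{rec.pos}; split upstream"
                )
            info = rec.info
            chrom, pos, ref, alt = left_normalize(
                rec.chrom, rec.pos, rec.ref, rec.alts[0]
            )

            def _scalar(key):
                if key not in info:
                    return None
                v = info[key]
                return v[0] if isinstance(v, tuple) else v

            vaf = _scalar("VAF")
            sites.append(
                VariantSite(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    var_type=_scalar("TYPE"),
                    gene=_scalar("GENE"),
                    vaf_ewgs=float(vaf) if vaf is not None else None,
                    subclone=_scalar("SUBCLONE"),
                )
            )
    return sites


_SUFFIX_RE = re.compile(r"-\d+$")


def load_barcodes(path: str, strip_suffix: bool = False) -> set[str]:
    """Load a filtered cell-barcode list (one barcode per line).

    Cell Ranger lists may carry a ``-1`` GEM-group suffix; ``strip_suffix``
    normalizes it away so lists of either dialect compare equal.
    """
    barcodes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            bc = line.strip()
            if not bc:
                continue
            if strip_suffix:
                bc = _SUFFIX_RE.sub("", bc)
            barcodes.add(bc)
    return barcodes


def normalize_barcode(bc: str, strip_suffix: bool = False) -> str:
    return _SUFFIX_RE.sub("", bc) if strip_suffix else bc


def write_variants_vcf(sites: Iterable[VariantSite], path: str,
                       contigs: dict[str, int] | None = None) -> None:
    """Write variant sites to an uncompressed VCF (used by the simulator)."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=VAF,Number=1,Type=Float,Description="Bulk DNA VAF">')
    header.add_line('##INFO=<ID=SUBCLONE,Number=1,Type=String,Description="Clone label">')
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line('##INFO=<ID=TYPE,Number=1,Type=String,Description="snv/insertion/deletion">')
    sites = list(sites)
    if contigs is None:
        contigs = {}
        for s in sites:
            contigs[s.chrom] = max(contigs.get(s.chrom, 0), s.pos + len(s.ref) + 1000)
    for name, length in contigs.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    with pysam.VariantFile(path, "w", header=header) as out:
        for s in sites:
            rec = out.new_record(
                contig=s.chrom, start=s.pos0, alleles=(s.ref, s.alt)
            )
            if s.vaf_ewgs is not None:
                rec.info["VAF"] = s.vaf_ewgs
            if s.subclone is not None:
                rec.info["SUBCLONE"] = s.subclone
            if s.gene is not None:
                rec.info["GENE"] = s.gene
            rec.info["TYPE"] = s.var_type
            out.write(rec)
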