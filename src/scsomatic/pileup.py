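"""Barcode/UMI-aware allele extraction at known variant sites.

Reads sharing a (cell barcode, UMI) pair are PCR copies of one cDNA
molecule, so allele evidence is collapsed to one consensus call per
molecule: if the reads in a group disagree at the variant base, the modal
base is accepted when it makes up at least 75% of the reads, otherwise
the whole group is discarded.  SNV evidence is the aligned base at the
site; indel evidence is a cigar insertion/deletion of the expected length
placed within a small window of the site (droplet reads in repetitive
regions are frequently misaligned by a few bases).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam

from scsomatic.variants import DELETION, INSERTION, SNV, VariantSite, normalize_barcode

REF = "ref"
ALT = "alt"
OTHER = "other"
DISCARDED = "discarded"

CONSENSUS_THRESHOLD = 0.75  # inclusive: modal base at >= 75% of reads wins

_CIGAR_OPS = "MIDNSHP=XB"


@dataclass
class TaggedRead:
    """Minimal view of one aligned read at (or near) a variant site."""

    cell_barcode: str | None
    umi: str | None
    base_at_site: str | None
    base_quality: int
    mapping_quality: int
    cigar: list[tuple[str, int]] = field(default_factory=list)
    reference_start: int = 0  # 0-based leftmost aligned reference position
    query_name: str | None = None

    def __post_init__(self):
        if self.base_quality < 0 or self.mapping_quality < 0:
            raise ValueError("qualities must be non-negative")

    @property
    def reference_span(self) -> tuple[int, int]:
        """0-based half-open reference interval consumed by the alignment."""
        end = self.reference_start
        for op, length in self.cigar:
            if op in "MDN=X":
                end += length
        return self.reference_start, end


@dataclass(frozen=True)
class UMICall:
    """Consensus allele for one (cell barcode, UMI) group at one site."""

    cell_barcode: str
    umi: str
    allele: str  # ref | alt | other | discarded
    read_count: int
    discordant: bool

    def __post_init__(self):
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")
        if self.allele == DISCARDED and not self.discordant:
            raise ValueError("discarded calls must be discordant")


def filter_reads(
    reads: Iterable[TaggedRead],
    site: VariantSite,
    barcodes: set[str] | None = None,
    min_baseq: int = 1,
    min_mapq: int = 1,
    strip_suffix: bool = False,
) -> list[TaggedRead]:
    """Apply the tag/quality/barcode filters.

    A read is kept only if it carries both a cell barcode and a UMI, its
    base quality and mapping quality are both at or above the thresholds
    (default 1, i.e. quality-0 evidence is dropped), and — when a filtered
    barcode list is supplied — its cell barcode is on that list.  Mate
    pairs are deduplicated by query name (one molecule observation per
    read pair) keeping the higher-base-quality mate.
    """
    kept: list[TaggedRead] = []
    for r in reads:
        if r.cell_barcode is None or r.umi is None:
            continue
        if r.base_quality < min_baseq or r.mapping_quality < min_mapq:
            continue
        if barcodes is not None:
            if normalize_barcode(r.cell_barcode, strip_suffix) not in barcodes:
                continue
        kept.append(r)
    # query-name dedup so paired mates do not double-count one observation
    by_name: dict[str, TaggedRead] = {}
    anon: list[TaggedRead] = []
    for r in kept:
        if r.query_name is None:
            anon.append(r)
        elif (r.query_name not in by_name
              or r.base_quality > by_name[r.query_name].base_quality):
            by_name[r.query_name] = r
    return anon + list(by_name.values())


def _consensus_label(labels: Sequence[str]) -> tuple[str | None, bool, int]:
    """Collapse per-read labels to (consensus label, discordant, n_reads).

    Returns label ``None`` when the group is discarded (no label reaches
    the 75% consensus threshold).
    """
    n = len(labels)
    if n == 0:
        raise ValueError("empty UMI group")
    counts = Counter(labels)
    label, top = counts.most_common(1)[0]
    discordant = len(counts) > 1
    if not discordant:
        return label, False, n
    if top / n >= CONSENSUS_THRESHOLD:
        return label, True, n
    return None, True, n


def consensus_umi(group: Sequence[TaggedRead], site: VariantSite) -> UMICall:
    """Consensus SNV call for one (cell barcode, UMI) read group."""
    if not group:
        raise ValueError("empty UMI group")
    cb, umi = group[0].cell_barcode, group[0].umi
    if any(r.cell_barcode != cb or r.umi != umi for r in group):
        raise ValueError("group mixes (cell barcode, UMI) pairs")
    bases = [r.base_at_site for r in group if r.base_at_site is not None]
    if not bases:
        raise ValueError("no base evidence in group")
    base, discordant, _ = _consensus_label(bases)
    allele = _classify_base(base, site) if base is not None else DISCARDED
    return UMICall(cb, umi, allele, len(bases), discordant)


def _classify_base(base: str, site: VariantSite) -> str:
    if base == site.ref:
        return REF
    if base == site.alt:
        return ALT
    return OTHER


def _group_by_molecule(reads: Iterable[TaggedRead]):
    groups: dict[tuple[str, str], list[TaggedRead]] = defaultdict(list)
    for r in reads:
        groups[(r.cell_barcode, r.umi)].append(r)
    return groups


def call_snv_alleles(
    site: VariantSite,
    reads: Iterable[TaggedRead],
    barcodes: set[str] | None = None,
    min_baseq: int = 1,
    min_mapq: int = 1,
    strip_suffix: bool = False,
) -> list[UMICall]:
    """Filter, group by molecule and call consensus alleles at an SNV site."""
    if site.var_type != SNV:
        raise ValueError("call_snv_alleles requires an SNV site")
    kept = filter_reads(reads, site, barcodes, min_baseq, min_mapq, strip_suffix)
    kept = [r for r in kept if r.base_at_site is not None]
    return [consensus_umi(grp, site)
            for grp in _group_by_molecule(kept).values()]


def indel_read_support(read: TaggedRead, site: VariantSite, window: int) -> str | None:
    """Label one read's indel evidence: 'alt', 'ref', 'other' or None.

    'alt': the cigar contains an insertion/deletion op of the expected
    type and length whose reference placement lies within ±window of the
    variant; 'ref': the alignment spans the variant interval with no
    indel op in the window; 'other': an indel of the wrong length or type
    sits in the window; None: the read is uninformative (does not span).
    """
    if site.var_type not in (INSERTION, DELETION):
        raise ValueError("indel support requires an indel site")
    expected_op = "I" if site.var_type == INSERTION else "D"
    target = site.pos0 + 1  # first inserted/deleted reference position
    ref_pos = read.reference_start
    found_alt = False
    found_other = False
    has_indel = False
    for op, length in read.cigar:
        if op in "M=X":
            ref_pos += length
        elif op == "I":
            has_indel = True
            if abs(ref_pos - target) <= window:
                if expected_op == "I" and length == site.indel_length:
                    found_alt = True
                else:
                    found_other = True
        elif op in "DN":
            if op == "D":
                has_indel = True
                if abs(ref_pos - target) <= window:
                    if expected_op == "D" and length == site.indel_length:
                        found_alt = True
                    else:
                        found_other = True
            ref_pos += length
        # S/H/P consume neither reference nor matter here
    if found_alt:
        return ALT
    if found_other:
        return OTHER
    if has_indel:
        # an indel-bearing read whose event falls outside the window is
        # uninformative: it is neither clean reference nor site evidence
        return None
    start, end = read.reference_span
    if start <= site.pos0 and end >= site.pos0 + len(site.ref):
        return REF
    return None


def call_indel_alleles(
    site: VariantSite,
    reads: Iterable[TaggedRead],
    window: int = 10,
    barcodes: set[str] | None = None,
    min_baseq: int = 1,
    min_mapq: int = 1,
    strip_suffix: bool = False,
) -> list[UMICall]:
    """Cigar-based indel calling with the per-molecule consensus rule."""
    if window < 0:
        raise ValueError("window must be >= 0")
    kept = filter_reads(reads, site, barcodes, min_baseq, min_mapq, strip_suffix)
    calls: list[UMICall] = []
    for (cb, umi), grp in _group_by_molecule(kept).items():
        labels = [lab for r in grp
                  if (lab := indel_read_support(r, site, window)) is not None]
        if not labels:
            continue
        label, discordant, n = _consensus_label(labels)
        allele = label if label is not None else DISCARDED
        calls.append(UMICall(cb, umi, allele, n, discordant))
    return calls


def call_site(site: VariantSite, reads, **kwargs) -> list[UMICall]:
    """Dispatch to the SNV or indel caller based on the site type."""
    if site.var_type == SNV:
        kwargs.pop("window", None)
        return call_snv_alleles(site, reads, **kwargs)
    return call_indel_alleles(site, reads, **kwargs)


def discordance_rate(calls: Sequence[UMICall]) -> float:
    """Fraction of UMI groups whose duplicate reads disagreed at the site."""
    if len(calls) == 0:
        raise ValueError("discordance rate undefined for zero UMI groups")
    return sum(c.discordant for c in calls) / len(calls)


# ---------------------------------------------------------------------------
# BAM adapter


def _tagged_read_from_segment(seg: pysam.AlignedSegment, site: VariantSite) -> TaggedRead:
    cb = seg.get_tag("CB") if seg.has_tag("CB") else None
    ub = seg.get_tag("UB") if seg.has_tag("UB") else None
    base = None
    baseq = 0
    seq = seg.query_sequence
    quals = seg.query_qualities
    if seq is not None:
        for qpos, rpos in seg.get_aligned_pairs(matches_only=True):
            if rpos == site.pos0:
                base = seq[qpos]
                baseq = int(quals[qpos]) if quals is not None else 0
                break
    cigar = [(_CIGAR_OPS[op], length) for op, length in (seg.cigartuples or [])]
    return TaggedRead(
        cell_barcode=cb,
        umi=ub,
        base_at_site=base,
        base_quality=baseq,
        mapping_quality=seg.mapping_quality,
        cigar=cigar,
        reference_start=seg.reference_start,
        query_name=seg.query_name,
    )


def fetch_tagged_reads(
    aln: pysam.AlignmentFile, site: VariantSite, window: int = 10
) -> list[TaggedRead]:
    """Extract tagged reads overlapping a site (± window for indels)."""
    if site.chrom not in aln.references:
        raise ValueError(f"contig {site.chrom!r} not in alignment header")
    clen = aln.get_reference_length(site.chrom)
    if site.pos0 >= clen:
        raise ValueError(f"position {site.pos} beyond contig {site.chrom} ({clen} bp)")
    pad = window if site.var_type != SNV else 0
    start = max(0, site.pos0 - pad)
    end = min(clen, site.pos0 + len(site.ref) + pad)
    reads = []
    for seg in aln.fetch(site.chrom, start, end):
        if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
            continue
        tr = _tagged_read_from_segment(seg, site)
        if site.var_type != SNV and tr.base_at_site is None:
            # indel evidence needs no aligned base at the anchor; give such
            # reads a pass on the base-quality gate via their mean quality
            qs = seg.query_qualities
            tr.base_quality = int(round(sum(qs) / len(qs))) if qs else 1
        reads.append(tr)
    return reads


def _collect_reads_linear(
    aln: pysam.AlignmentFile, sites: Sequence[VariantSite], window: int
) -> dict[str, list[TaggedRead]]:
    """One streaming pass for un-indexed SAM input."""
    refs = set(aln.references)
    intervals = []
    for site in sites:
        if site.chrom not in refs:
            raise ValueError(f"contig {site.chrom!r} not in alignment header")
        if site.pos0 >= aln.get_reference_length(site.chrom):
            raise ValueError(f"position {site.pos} beyond contig {site.chrom}")
        pad = window if site.var_type != SNV else 0
        intervals.append((site, site.pos0 - pad, site.pos0 + len(site.ref) + pad))
    by_site: dict[str, list[TaggedRead]] = {s.key: [] for s in sites}
    for seg in aln.fetch(until_eof=True):
        if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
            continue
        for site, start, end in intervals:
            if (seg.reference_name == site.chrom
                    and seg.reference_start < end
                    and seg.reference_end is not None
                    and seg.reference_end > start):
                tr = _tagged_read_from_segment(seg, site)
                if site.var_type != SNV and tr.base_at_site is None:
                    qs = seg.query_qualities
                    tr.base_quality = (
                        int(round(sum(qs) / len(qs))) if qs else 1)
                by_site[site.key].append(tr)
    return by_site


def pileup_bam(
    bam_path: str,
    sites: Iterable[VariantSite],
    barcodes: set[str] | None = None,
    min_baseq: int = 1,
    min_mapq: int = 1,
    indel_window: int = 10,
    strip_suffix: bool = False,
) -> dict[str, list[UMICall]]:
    """Run the full pileup over a SAM/BAM file.

    Indexed BAMs are random-accessed per site; un-indexed (e.g. plain
    SAM) input is handled with a single streaming pass.  Returns a
    mapping from ``VariantSite.key`` to the site's UMI calls.
    """
    sites = list(sites)
    out: dict[str, list[UMICall]] = {}
    with pysam.AlignmentFile(bam_path) as aln:
        if aln.has_index():
            reads_by_site = {
                s.key: fetch_tagged_reads(aln, s, window=indel_window)
                for s in sites
            }
        else:
            reads_by_site = _collect_reads_linear(aln, sites, indel_window)
    for site in sites:
        out[site.key] = call_site(
            site,
            reads_by_site[site.key],
            barcodes=barcodes,
            min_baseq=min_baseq,
            min_mapq=min_mapq,
            strip_suffix=strip_suffix,
            **({"window": indel_window} if site.var_type != SNV else {}),
        )
    return out


def write_calls_tsv(calls_by_site: dict[str, list[UMICall]], path: str) -> None:
    """Write per-molecule allele calls as TSV."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["chrom", "pos", "ref", "alt", "cell_barcode", "umi",
                    "allele", "read_count", "discordant"])
        for key, calls in calls_by_site.items():
            chrom, pos, ref, alt = key.rsplit(":", 3)
            for c in calls:
                w.writerow([chrom, pos, ref, alt, c.cell_barcode, c.umi,
                            c.allele, c.read_count, int(c.discordant)])


def read_calls_tsv(path: str) -> dict[str, list[UMICall]]:
    import csv

    out: dict[str, list[UMICall]] = defaultdict(list)
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            key = f"{row['chrom']}:{row['pos']}:{row['ref']}:{row['alt']}"
            out[key].append(UMICall(
                cell_barcode=row["cell_barcode"],
                umi=row["umi"],
                allele=row["allele"],
                read_count=int(row["read_count"]),
                discordant=bool(int(row["discordant"])),
            ))
    return dict(out)
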