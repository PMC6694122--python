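"""Synthetic tagged reads, variant tables and expression matrices.

The generator emulates the data-generating process the detection model
assumes: cells are tumor or normal; tumor cells sit on a clone tree and
carry the variants on their root-to-node path; each cell emits
Poisson-distributed UMIs per gene; in a heterozygous carrier each
molecule comes from the mutant allele with probability 0.5 (allelic
dropout); a molecule's reads cover the variant position with the
site-coverage probability; PCR duplicates and per-read sequencing errors
are layered on top.  Emitted SAM/VCF/barcode files round-trip through
the pileup and genotyping modules, and the per-cell ground truth is
retained so precision, sensitivity and error rates can be scored
exactly.

All randomness flows through one ``numpy`` generator seeded from the
mandatory config seed, so identical configs give identical outputs.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from scsomatic.variants import (
    DELETION,
    INSERTION,
    SNV,
    VariantSite,
    write_variants_vcf,
)

BASES = "ACGT"


@dataclass(frozen=True)
class GeneSpec:
    """One simulated gene: its own contig with the spliced transcript."""

    name: str
    length: int = 3000
    cpm: float = 500.0  # relative expression in counts per million


@dataclass(frozen=True)
class VariantSpec:
    """One somatic variant planted in a gene."""

    gene: str
    offset: int = 1500  # 0-based position of the (anchor) base in the gene
    var_type: str = SNV
    indel_length: int = 4  # ignored for SNVs
    site_coverage: float | None = None  # override config-wide c


@dataclass(frozen=True)
class CloneSpec:
    """Clone-tree node: fraction is of the parent's cells."""

    name: str
    parent: str | None  # None for the founding clone
    fraction: float
    variants: tuple[str, ...] = ()  # gene names of this node's variants


def default_clone_tree() -> tuple[CloneSpec, ...]:
    return (
        CloneSpec("founding", None, 1.0, ("DNMT3A", "NPM1")),
        CloneSpec("subclone1", "founding", 0.3, ("GATA2",)),
    )


def default_genes() -> tuple[GeneSpec, ...]:
    return (
        GeneSpec("DNMT3A", length=3000, cpm=300.0),
        GeneSpec("NPM1", length=1500, cpm=3000.0),
        GeneSpec("GATA2", length=3000, cpm=500.0),
    )


def default_variants() -> tuple[VariantSpec, ...]:
    return (
        VariantSpec("DNMT3A", offset=1500, var_type=SNV),
        VariantSpec("NPM1", offset=700, var_type=INSERTION, indel_length=4),
        VariantSpec("GATA2", offset=1200, var_type=SNV),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the read simulator; ``seed`` is mandatory.

    Defaults mirror a typical droplet 5' AML bone-marrow run: ~18,000
    cells of which half are tumor, ~2,000 UMIs per cell, 2.5% of a
    gene's molecules covering any given base, and a 0.1% per-read error
    at the variant base.
    """

    seed: int
    n_cells: int = 17_965
    tumor_fraction: float = 0.5
    umis_per_cell: float = 2000.0  # r; per-gene rate is r * cpm / 1e6
    site_coverage: float = 0.025  # c
    error_rate: float = 0.001  # e, per read at the variant base
    het_prob: float = 0.5  # P(molecule is mutant | carrier); 1.0 = homozygous
    duplicate_fraction: float = 0.1  # P(a molecule gets one extra read)
    inject_discordance: float = 0.0  # P(a covering molecule gets a forced
    # duplicate whose site base disagrees)
    low_quality_fraction: float = 0.0  # reads emitted with base quality 0
    untagged_fraction: float = 0.0  # reads emitted without CB/UB tags
    read_length: int = 90
    barcode_length: int = 16
    umi_length: int = 10
    genes: tuple[GeneSpec, ...] = field(default_factory=default_genes)
    variants: tuple[VariantSpec, ...] = field(default_factory=default_variants)
    clones: tuple[CloneSpec, ...] = field(default_factory=default_clone_tree)

    def __post_init__(self):
        for name in ("tumor_fraction", "site_coverage", "het_prob",
                     "duplicate_fraction", "inject_discordance",
                     "low_quality_fraction", "untagged_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        by_parent: dict[str | None, float] = {}
        names = {c.name for c in self.clones}
        for c in self.clones:
            if c.parent is not None and c.parent not in names:
                raise ValueError(f"clone {c.name!r} has unknown parent")
            if not 0.0 <= c.fraction <= 1.0:
                raise ValueError("clone fractions must lie in [0, 1]")
            by_parent[c.parent] = by_parent.get(c.parent, 0.0) + c.fraction
        for parent, total in by_parent.items():
            if parent is not None and total > 1.0 + 1e-9:
                raise ValueError(
                    f"children of {parent!r} have fractions summing to {total} > 1")


@dataclass
class TruthTable:
    """Ground truth of one simulation."""

    cells: pd.DataFrame  # cell_barcode, is_tumor, clone
    genotype: pd.DataFrame  # cells × variant keys, bool
    sites: dict[str, VariantSite]  # variant key -> site (with true VAF)
    site_fp_rate: dict[str, float]  # P(wild-type molecule called alt), 1 read
    config: SimulationConfig


# ---------------------------------------------------------------------------


def _random_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        need = n - len(out)
        draws = rng.integers(0, 4, size=(need, length))
        for row in draws:
            bc = "".join(BASES[i] for i in row)
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def _clone_children(clones: Sequence[CloneSpec]) -> dict[str | None, list[CloneSpec]]:
    children: dict[str | None, list[CloneSpec]] = {}
    for c in clones:
        children.setdefault(c.parent, []).append(c)
    return children


def _clone_paths(clones: Sequence[CloneSpec]) -> dict[str, list[CloneSpec]]:
    by_name = {c.name: c for c in clones}
    paths = {}
    for c in clones:
        path, node = [], c
        while True:
            path.append(node)
            if node.parent is None:
                break
            node = by_name[node.parent]
        paths[c.name] = path[::-1]
    return paths


def simulate_cells(config: SimulationConfig) -> TruthTable:
    """Assign tumor status, clone membership and genotypes to cells."""
    rng = np.random.default_rng(config.seed)
    barcodes = _random_barcodes(rng, config.n_cells, config.barcode_length)
    is_tumor = rng.random(config.n_cells) < config.tumor_fraction

    children = _clone_children(config.clones)
    roots = children.get(None, [])
    if len(roots) != 1:
        raise ValueError("clone tree needs exactly one founding clone")
    root = roots[0]

    def assign(node: CloneSpec) -> str:
        kids = children.get(node.name, [])
        if kids:
            u = rng.random()
            acc = 0.0
            for kid in kids:
                acc += kid.fraction
                if u < acc:
                    return assign(kid)
        return node.name

    clone = np.array([assign(root) if t else "" for t in is_tumor], dtype=object)

    paths = _clone_paths(config.clones)
    gene_variants = {v.gene: v for v in config.variants}
    site_keys, sites, fp_rates = _variant_sites(config)
    geno = pd.DataFrame(
        False, index=barcodes, columns=[site_keys[v.gene] for v in config.variants]
    )
    for i, bc in enumerate(barcodes):
        if not is_tumor[i]:
            continue
        for node in paths[clone[i]]:
            for gene in node.variants:
                geno.loc[bc, site_keys[gene_variants[gene].gene]] = True

    cells = pd.DataFrame({
        "cell_barcode": barcodes,
        "is_tumor": is_tumor,
        "clone": clone,
    })
    # true bulk-DNA VAF of each variant: half the carrier fraction among
    # all cells (heterozygous), or the carrier fraction itself if the
    # simulation is run in homozygous mode
    allele_factor = 0.5 if config.het_prob <= 0.5 else config.het_prob
    for v in config.variants:
        key = site_keys[v.gene]
        carrier_frac = geno[key].mean()
        sites[key] = replace(sites[key], vaf_ewgs=float(allele_factor * carrier_frac))
    return TruthTable(
        cells=cells, genotype=geno, sites=sites, site_fp_rate=fp_rates,
        config=config,
    )


def _reference_sequences(config: SimulationConfig) -> dict[str, str]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    return {
        g.name: "".join(BASES[i] for i in rng.integers(0, 4, size=g.length))
        for g in config.genes
    }


def _variant_sites(config: SimulationConfig):
    """Variant keys, VariantSite objects and true per-site FP rates."""
    refs = _reference_sequences(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    site_keys: dict[str, str] = {}
    sites: dict[str, VariantSite] = {}
    fp: dict[str, float] = {}
    clone_of_gene = {}
    for c in config.clones:
        for gene in c.variants:
            clone_of_gene[gene] = c.name
    for v in config.variants:
        seq = refs[v.gene]
        anchor = seq[v.offset]
        if v.var_type == SNV:
            alt = BASES[(BASES.index(anchor) + 1 + rng.integers(0, 3)) % 4]
            ref_allele, alt_allele = anchor, alt
            # a wrong read of a wild-type base lands on the alt base 1/3
            # of the time (errors are uniform over the three other bases)
            fp_rate = config.error_rate / 3.0
        elif v.var_type == INSERTION:
            ins = "".join(BASES[i] for i in rng.integers(0, 4, size=v.indel_length))
            ref_allele, alt_allele = anchor, anchor + ins
            fp_rate = 0.0  # substitution errors cannot fake a cigar indel
        elif v.var_type == DELETION:
            ref_allele = seq[v.offset:v.offset + 1 + v.indel_length]
            alt_allele = anchor
            fp_rate = 0.0
        else:
            raise ValueError(f"unknown var_type {v.var_type!r}")
        site = VariantSite(
            chrom=v.gene, pos=v.offset + 1, ref=ref_allele, alt=alt_allele,
            gene=v.gene, subclone=clone_of_gene.get(v.gene),
        )
        site_keys[v.gene] = site.key
        sites[site.key] = site
        fp[site.key] = fp_rate
    return site_keys, sites, fp


# ---------------------------------------------------------------------------
# Read emission


def _snv_read(rng, seq, site_pos0, true_base, read_length, gene_length, cover, e):
    """(start, cigar, sequence, base) for one SNV-gene read."""
    if cover:
        lo = max(0, site_pos0 - read_length + 1)
        hi = min(site_pos0, gene_length - read_length)
        start = int(rng.integers(lo, hi + 1))
    else:
        while True:
            start = int(rng.integers(0, gene_length - read_length + 1))
            if not (start <= site_pos0 < start + read_length):
                break
    bases = list(seq[start:start + read_length])
    base = None
    if cover:
        base = true_base
        if e > 0 and rng.random() < e:
            base = BASES[(BASES.index(base) + 1 + int(rng.integers(0, 3))) % 4]
        bases[site_pos0 - start] = base
    return start, [("M", read_length)], "".join(bases), base


def _indel_read(rng, seq, site: VariantSite, read_length, gene_length, cover, alt):
    """(start, cigar, sequence) for one indel-gene read."""
    pos0 = site.pos0
    dlen = site.indel_length
    if not cover:
        while True:
            start = int(rng.integers(0, gene_length - read_length + 1))
            if not (start <= pos0 + len(site.ref) and start + read_length > pos0):
                break
        return start, [("M", read_length)], seq[start:start + read_length]
    margin = 10
    a = int(rng.integers(margin, read_length - margin))  # bases before the event
    if site.var_type == INSERTION and alt:
        start = pos0 + 1 - a
        b = read_length - a - dlen
        if b < 1:
            b, a = 1, read_length - 1 - dlen
            start = pos0 + 1 - a
        inserted = site.alt[1:]
        sequence = seq[start:pos0 + 1] + inserted + seq[pos0 + 1:pos0 + 1 + b]
        cigar = [("M", a), ("I", dlen), ("M", b)]
    elif site.var_type == DELETION and alt:
        start = pos0 + 1 - a
        b = read_length - a
        del_end = pos0 + 1 + dlen
        sequence = seq[start:pos0 + 1] + seq[del_end:del_end + b]
        cigar = [("M", a), ("D", dlen), ("M", b)]
    else:  # reference molecule spanning the site
        start = max(0, pos0 + 1 + dlen - read_length + margin)
        start = min(start, max(0, pos0 - margin))
        start = max(0, min(start, gene_length - read_length))
        sequence = seq[start:start + read_length]
        cigar = [("M", read_length)]
    return start, cigar, sequence


def simulate_reads(truth: TruthTable, out_dir: str) -> dict[str, str]:
    """Emit tagged SAM records, a VCF, a barcode list and truth tables.

    Returns a dict of output paths.  The SAM is coordinate-sorted text;
    the reference FASTA for the simulated gene contigs is written
    alongside so headers are self-consistent.  An ``emitted.tsv`` truth
    table records, per (cell, variant), how many covering mutant and
    wild-type molecules were actually emitted — the exact expectation
    for a zero-error round trip.
    """
    config = truth.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    refs = _reference_sequences(config)
    os.makedirs(out_dir, exist_ok=True)

    gene_specs = {g.name: g for g in config.genes}
    site_by_gene = {s.gene: s for s in truth.sites.values()}
    barcodes = truth.cells.cell_barcode.to_numpy()
    n_cells = len(barcodes)

    records = []  # (contig, start, cigar, seq, cb, ub, lowq)
    emitted_rows = []
    umi_counter = 0

    for gene in config.genes:
        seq = refs[gene.name]
        lam = config.umis_per_cell * gene.cpm / 1e6
        umi_counts = rng.poisson(lam, size=n_cells)
        site = site_by_gene.get(gene.name)
        key = site.key if site is not None else None
        c = config.site_coverage
        if site is not None:
            for v in config.variants:
                if v.gene == gene.name and v.site_coverage is not None:
                    c = v.site_coverage
        carrier = (truth.genotype[key].to_numpy() if key is not None
                   else np.zeros(n_cells, dtype=bool))
        for i in np.nonzero(umi_counts)[0]:
            cb = barcodes[i]
            for _ in range(int(umi_counts[i])):
                umi_counter += 1
                ub = _int_to_umi(umi_counter, config.umi_length)
                is_mut = bool(carrier[i] and rng.random() < config.het_prob)
                covers = bool(site is not None and rng.random() < c)
                n_reads = 1 + int(rng.random() < config.duplicate_fraction)
                force_discord = bool(
                    covers and site is not None and site.var_type == SNV
                    and rng.random() < config.inject_discordance
                )
                if force_discord and n_reads < 2:
                    n_reads = 2
                if covers:
                    emitted_rows.append((cb, key, int(is_mut)))
                for j in range(n_reads):
                    if site is None or site.var_type == SNV:
                        true_base = (site.alt if is_mut else site.ref) if site else None
                        start, cigar, sequence, _ = _snv_read(
                            rng, seq,
                            site.pos0 if site else 0,
                            true_base or "A",
                            config.read_length, gene.length,
                            covers and site is not None,
                            config.error_rate,
                        )
                        if force_discord and j == n_reads - 1:
                            # rewrite the site base to a disagreeing one
                            p = (site.pos0 - start)
                            cur = sequence[p]
                            other = BASES[(BASES.index(cur) + 1) % 4]
                            sequence = sequence[:p] + other + sequence[p + 1:]
                    else:
                        start, cigar, sequence = _indel_read(
                            rng, seq, site, config.read_length, gene.length,
                            covers, is_mut,
                        )
                    lowq = rng.random() < config.low_quality_fraction
                    untagged = rng.random() < config.untagged_fraction
                    records.append((gene.name, start, cigar, sequence,
                                    None if untagged else cb,
                                    None if untagged else ub, lowq))

    paths = _write_outputs(config, truth, refs, records, emitted_rows, out_dir)
    return paths


def _int_to_umi(n: int, length: int) -> str:
    digits = []
    for _ in range(length):
        digits.append(BASES[n % 4])
        n //= 4
    return "".join(digits)


def _write_outputs(config, truth, refs, records, emitted_rows, out_dir):
    sam_path = os.path.join(out_dir, "alignments.sam")
    vcf_path = os.path.join(out_dir, "variants.vcf")
    bc_path = os.path.join(out_dir, "barcodes.txt")
    fa_path = os.path.join(out_dir, "reference.fa")
    truth_cells_path = os.path.join(out_dir, "truth_cells.tsv")
    truth_geno_path = os.path.join(out_dir, "truth_genotypes.tsv")
    emitted_path = os.path.join(out_dir, "emitted.tsv")

    contigs = {g.name: g.length for g in config.genes}
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
    })
    order = {name: i for i, name in enumerate(contigs)}
    records.sort(key=lambda r: (order[r[0]], r[1]))
    with pysam.AlignmentFile(sam_path, "w", header=header) as out:
        for k, (contig, start, cigar, seq, cb, ub, lowq) in enumerate(records):
            a = pysam.AlignedSegment(header)
            a.query_name = f"read{k}"
            a.reference_name = contig
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = "".join(f"{ln}{op}" for op, ln in cigar)
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(
                ("!" if lowq else "F") * len(seq))
            a.flag = 0
            tags = []
            if cb is not None:
                tags.append(("CB", cb))
            if ub is not None:
                tags.append(("UB", ub))
            a.set_tags(tags)
            out.write(a)

    write_variants_vcf(truth.sites.values(), vcf_path, contigs=contigs)
    with open(bc_path, "w") as fh:
        fh.write("\n".join(truth.cells.cell_barcode) + "\n")
    with open(fa_path, "w") as fh:
        for name, seq in refs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    truth.cells.to_csv(truth_cells_path, sep="\t", index=False)
    truth.genotype.to_csv(truth_geno_path, sep="\t")
    emitted = pd.DataFrame(emitted_rows, columns=["cell_barcode", "site", "is_mut"])
    emitted = (emitted.groupby(["cell_barcode", "site"])["is_mut"]
               .agg(alt_umis="sum", total_umis="count").reset_index())
    emitted.to_csv(emitted_path, sep="\t", index=False)
    return {
        "sam": sam_path, "vcf": vcf_path, "barcodes": bc_path,
        "reference": fa_path, "truth_cells": truth_cells_path,
        "truth_genotypes": truth_geno_path, "emitted": emitted_path,
    }


def simulate(config: SimulationConfig, out_dir: str):
    """Convenience wrapper: simulate cells then reads."""
    truth = simulate_cells(config)
    paths = simulate_reads(truth, out_dir)
    return truth, paths


# ---------------------------------------------------------------------------
# Expression matrices with a planted mutant-density signature


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Cluster-structured counts with a planted density signature.

    Signature genes' cluster-mean log expression rises linearly with the
    cluster's mutant-cell fraction m (slope ``effect_size``); all other
    genes are flat.  Cells add log-normal noise around their cluster
    mean and counts are Poisson at the target depth.
    """

    seed: int
    n_clusters: int = 12
    cells_per_cluster: int = 100
    n_genes: int = 1000
    n_signature_genes: int = 50
    effect_size: float = 1.5  # slope y on m, log-expression units
    noise_sd: float = 0.2  # log-normal cell-level noise
    baseline: float = 1.0  # baseline log-expression
    target_depth: float = 10_000.0
    mutant_fractions: tuple[float, ...] | None = None  # per cluster m

    def m_values(self) -> np.ndarray:
        if self.mutant_fractions is not None:
            if len(self.mutant_fractions) != self.n_clusters:
                raise ValueError("need one mutant fraction per cluster")
            return np.asarray(self.mutant_fractions, dtype=float)
        return np.linspace(0.02, 0.6, self.n_clusters)


def simulate_expression(config: ExpressionSimConfig):
    """Returns (counts genes × cells, cluster_of dict, m per cluster, planted genes)."""
    if config.n_clusters < 4:
        raise ValueError("need at least 4 clusters")
    rng = np.random.default_rng(config.seed)
    m = config.m_values()
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    planted = genes[: config.n_signature_genes]
    mu = np.full((config.n_genes, config.n_clusters), config.baseline)
    mu[: config.n_signature_genes] += config.effect_size * m[None, :]

    cells, cluster_of = [], {}
    blocks = []
    for k in range(config.n_clusters):
        names = [f"C{k:02d}_{j:03d}" for j in range(config.cells_per_cluster)]
        cells.extend(names)
        for nme in names:
            cluster_of[nme] = k
        log_lam = (mu[:, [k]]
                   + rng.normal(0.0, config.noise_sd,
                                size=(config.n_genes, config.cells_per_cluster)))
        lam = np.exp(log_lam)
        lam *= config.target_depth / lam.sum(axis=0, keepdims=True)
        blocks.append(rng.poisson(lam))
    counts = pd.DataFrame(np.hstack(blocks), index=genes, columns=cells)
    m_per_cluster = pd.Series(m, index=range(config.n_clusters), name="m")
    return counts, cluster_of, m_per_cluster, planted


# ---------------------------------------------------------------------------
# Recovery report


def recovery_report(
    truth: TruthTable,
    genotypes: pd.DataFrame,
    emitted: pd.DataFrame,
    calls_by_site: Mapping[str, Sequence] | None = None,
) -> dict:
    """Score pipeline output against simulator truth.

    Returns a dict with genotype precision/recall (recall relative to
    cells for which at least one covering mutant molecule was actually
    emitted — molecules never emitted are invisible to any caller),
    observed vs expected mutant-cell counts per variant under the
    detection model (evaluated allele-aware: the coverage probability is
    thinned by the heterozygous sampling probability), and — when UMI
    calls are supplied — the estimated site false-positive rates over
    genuinely wild-type cells.
    """
    from scsomatic.detection import DetectionParams, expected_mutant_cells
    from scsomatic.genotyping import MUTANT, false_positive_rates

    config = truth.config
    report: dict = {"per_variant": {}}
    called_mut = genotypes[genotypes.status == MUTANT]
    emitted_mut = emitted[emitted.alt_umis > 0]
    detectable = set(zip(emitted_mut.cell_barcode, emitted_mut.site))
    called = set(zip(called_mut.cell_barcode, called_mut.site))
    true_carrier = {
        (bc, site)
        for site in truth.genotype.columns
        for bc in truth.genotype.index[truth.genotype[site]]
    }
    tp = len(called & true_carrier)
    report["genotype_precision"] = tp / len(called) if called else float("nan")
    report["genotype_recall"] = (
        len(called & detectable) / len(detectable) if detectable else float("nan")
    )

    gene_cpm = {g.name: g.cpm for g in config.genes}
    for key, site in truth.sites.items():
        carrier_frac_tumor = (
            truth.genotype.loc[truth.cells.is_tumor.values, key].mean()
            if truth.cells.is_tumor.any() else 0.0
        )
        params = DetectionParams(
            n=config.n_cells,
            a=config.tumor_fraction,
            f=float(carrier_frac_tumor),
            t=gene_cpm[site.gene] / 1e6,
            r=config.umis_per_cell,
            c=config.site_coverage * config.het_prob,
            e=truth.site_fp_rate[key],
        )
        observed = int((called_mut.site == key).sum())
        report["per_variant"][key] = {
            "observed_mutant_cells": observed,
            "expected_mutant_cells": expected_mutant_cells(params),
        }

    if calls_by_site is not None:
        wild = {
            key: [c for c in calls
                  if not truth.genotype.loc[c.cell_barcode, key]]
            for key, calls in calls_by_site.items()
        }
        report["estimated_fp_rate"] = false_positive_rates(wild)
        report["true_fp_rate"] = dict(truth.site_fp_rate)
    return report
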