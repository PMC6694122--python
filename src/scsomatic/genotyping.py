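"""Per-cell genotypes and sensitivity metrics.

Allelic dropout makes a wild-type call impossible from RNA: for a
heterozygous site there is only a 50% chance any sampled molecule carries
the mutant allele, so a cell with only reference molecules has genotype
"unknown", not wild-type.  A cell is therefore labeled ``mutant`` if at
least one consensus molecule carries the variant, ``ref_only`` if it has
coverage but only reference (or third-allele) molecules, and
``no_coverage`` otherwise.

Sensitivity metrics per variant:

* scVAF — variant molecules / all molecules at the site (read-based VAF
  pooled over cells; computed on UMI-consensus units by default, raw
  reads optionally).
* MCF — mutant cells M / cells with coverage T.
* MCDR — observed mutant cells / expected mutant cells, where the
  expectation is ``2 · VAF_DNA · T`` (a heterozygous variant at bulk-DNA
  VAF v should sit in ``2v`` of the covered cells).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from scsomatic.pileup import ALT, DISCARDED, OTHER, REF, UMICall
from scsomatic.variants import VariantSite

MUTANT = "mutant"
REF_ONLY = "ref_only"
NO_COVERAGE = "no_coverage"


def genotype_cells(
    calls_by_site: Mapping[str, Sequence[UMICall]],
    barcodes: Iterable[str],
) -> pd.DataFrame:
    """Build the cell × variant genotype table.

    Every barcode appears once per site with a status in
    {mutant, ref_only, no_coverage}.  Discarded (discordant) molecules are
    ignored; "other" (third-allele) molecules count as coverage but never
    as mutant or reference evidence.
    """
    barcodes = list(dict.fromkeys(barcodes))
    rows = []
    for site_key, calls in calls_by_site.items():
        tallies: dict[str, Counter] = defaultdict(Counter)
        for c in calls:
            if c.allele == DISCARDED:
                continue
            tallies[c.cell_barcode][c.allele] += 1
        for bc in barcodes:
            t = tallies.get(bc)
            alt_u = t[ALT] if t else 0
            ref_u = t[REF] if t else 0
            other_u = t[OTHER] if t else 0
            if alt_u >= 1:
                status = MUTANT
            elif ref_u + other_u >= 1:
                status = REF_ONLY
            else:
                status = NO_COVERAGE
            rows.append((bc, site_key, status, alt_u, ref_u, other_u))
    df = pd.DataFrame(
        rows,
        columns=["cell_barcode", "site", "status", "alt_umis", "ref_umis",
                 "other_umis"],
    )
    if df.duplicated(["cell_barcode", "site"]).any():
        raise ValueError("duplicate (cell, site) rows")
    return df


def scvaf(calls: Sequence[UMICall], raw_reads: bool = False) -> float:
    """Single-cell VAF at one site: alt units / (ref + alt + other units).

    The unit is one UMI-consensus molecule by default; with
    ``raw_reads=True`` each read in a non-discarded group counts.
    """
    alt = total = 0
    for c in calls:
        if c.allele == DISCARDED:
            continue
        w = c.read_count if raw_reads else 1
        total += w
        if c.allele == ALT:
            alt += w
    if total == 0:
        raise ValueError("scVAF undefined: no counted units at site")
    return alt / total


def mcf(M: int, T: int) -> float:
    """Mutant cell fraction M/T; T is the number of cells with coverage."""
    if T < 1:
        raise ValueError("MCF undefined: no cells with coverage")
    if M > T or M < 0:
        raise ValueError("need 0 <= M <= T")
    return M / T


def mcdr(M: int, T: int, vaf_ewgs: float | None) -> float:
    """Mutant cell detection rate: observed / (2 · VAF_DNA · T) expected.

    Uncapped — allele-specific expression or sampling can push it past 1.
    """
    if vaf_ewgs is None or vaf_ewgs == 0:
        raise ValueError("MCDR undefined without a nonzero bulk-DNA VAF")
    if T < 1:
        raise ValueError("MCDR undefined: no cells with coverage")
    return M / (2.0 * vaf_ewgs * T)


@dataclass(frozen=True)
class VariantMetrics:
    site: str
    M: int
    T: int
    scvaf: float
    mcf: float
    mcdr: float | None
    total_alt_umis: int
    total_umis: int


def variant_metrics(
    genotypes: pd.DataFrame,
    sites: Mapping[str, VariantSite] | None = None,
) -> pd.DataFrame:
    """Per-variant M, T, scVAF, MCF and MCDR from the genotype table."""
    out = []
    for site_key, g in genotypes.groupby("site", sort=False):
        covered = g[g.status != NO_COVERAGE]
        T = len(covered)
        M = int((g.status == MUTANT).sum())
        alt_u = int(g.alt_umis.sum())
        tot_u = int(g.alt_umis.sum() + g.ref_umis.sum() + g.other_umis.sum())
        vaf = sites[site_key].vaf_ewgs if sites and site_key in sites else None
        out.append(VariantMetrics(
            site=site_key,
            M=M,
            T=T,
            scvaf=alt_u / tot_u if tot_u else math.nan,
            mcf=mcf(M, T) if T else math.nan,
            mcdr=mcdr(M, T, vaf) if (T and vaf) else None,
            total_alt_umis=alt_u,
            total_umis=tot_u,
        ))
    return pd.DataFrame([m.__dict__ for m in out])


def tally_mutations(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Count mutant cells by number of distinct detected mutations.

    Returns one row per k >= 1 with the cell count and its percentage of
    all mutant cells (two significant figures, matching how such tallies
    are usually reported).
    """
    mut = genotypes[genotypes.status == MUTANT]
    per_cell = mut.groupby("cell_barcode")["site"].nunique()
    return tally_from_counts(Counter(per_cell.values))


def tally_from_counts(counts_by_k: Mapping[int, int]) -> pd.DataFrame:
    """Tally table from {k distinct mutations: number of mutant cells}."""
    total = sum(counts_by_k.values())
    ks = sorted(counts_by_k)
    rows = []
    for k in range(1, (max(ks) if ks else 0) + 1):
        n = counts_by_k.get(k, 0)
        pct = _round_sig(100.0 * n / total, 2) if total else math.nan
        rows.append((k, n, pct))
    df = pd.DataFrame(rows, columns=["n_mutations", "n_cells", "pct"])
    df.attrs["total_mutant_cells"] = total
    return df


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def assign_subclones(
    genotypes: pd.DataFrame,
    site_to_clone: Mapping[str, str],
    clone_parent: Mapping[str, str | None],
) -> pd.DataFrame:
    """Assign mutant cells to clone-tree nodes and flag inconsistent cells.

    Each mutant cell receives the set of clones whose mutations it
    expresses.  The set is *consistent* when it lies on a single
    root-to-leaf path of the clone tree (e.g. founding + nested subclone),
    and inconsistent when it mixes sibling branches.
    """
    for clone, parent in clone_parent.items():
        if parent is not None and parent not in clone_parent:
            raise ValueError(f"parent {parent!r} of {clone!r} not in tree")

    def ancestors(node: str) -> set[str]:
        seen = set()
        while node is not None:
            if node in seen:
                raise ValueError("clone tree contains a cycle")
            seen.add(node)
            node = clone_parent[node]
        return seen

    anc = {n: ancestors(n) for n in clone_parent}
    mut = genotypes[genotypes.status == MUTANT]
    unmapped = sorted(set(mut.site) - set(site_to_clone))
    if unmapped:
        import warnings

        warnings.warn(f"{len(unmapped)} site(s) not mapped to a clone; excluded")
    rows = []
    for bc, g in mut.groupby("cell_barcode"):
        clones = {site_to_clone[s] for s in g.site if s in site_to_clone}
        if not clones:
            continue
        # consistent iff some node's ancestor set contains every clone hit
        consistent = any(clones <= anc[c] for c in clones)
        rows.append((bc, tuple(sorted(clones)), consistent))
    return pd.DataFrame(rows, columns=["cell_barcode", "clones", "consistent"])


def false_positive_rates(
    control_calls_by_site: Mapping[str, Sequence[UMICall]],
) -> dict[str, float | None]:
    """Site-specific false-positive rates from control samples.

    Controls are samples known to lack the variants, so every alt-called
    unit is a sequencing/consensus error: rate = alt units / total units.
    Sites with no coverage in the controls get ``None``.
    """
    rates: dict[str, float | None] = {}
    for site_key, calls in control_calls_by_site.items():
        counted = [c for c in calls if c.allele != DISCARDED]
        if not counted:
            rates[site_key] = None
            continue
        rates[site_key] = sum(c.allele == ALT for c in counted) / len(counted)
    return rates
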