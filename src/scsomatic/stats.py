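"""Statistics linking single-cell genotypes to expression.

Covers the expression side of the pipeline: QC and depth normalization
of the counts matrix, nearest-neighbor lineage inference against
reference profiles, per-cluster mutant-cell enrichment (one-sided Fisher
exact tests), the mutant-density regression

    E_i = x_i + y_i·m + z_i·g

(per gene i, cluster-mean expression E regressed on the cluster's mutant
cell fraction m, optionally controlling for the mutated gene's own mean
expression g), Wilcoxon rank-sum signatures contrasting mutant-rich and
mutant-poor clusters, Pearson correlation screens against an anchor gene
in bulk cohorts, and hypergeometric gene-set overlap.

Multiple testing uses Benjamini-Hochberg throughout (the enrichment
Fisher tests are reported uncorrected by default, with BH optional).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from scsomatic.genotyping import MUTANT

# --------------------------------------------------------------------------
# QC and normalization

RIBO_PREFIXES = ("RPS", "RPL")
MITO_PREFIX = "MT-"


def qc_normalize(
    counts: pd.DataFrame,
    min_genes: int = 10,
    max_ribo_frac: float = 0.50,
    max_mito_frac: float = 0.10,
    min_cells_per_gene: int = 3,
    scale: float = 10_000.0,
) -> pd.DataFrame:
    """Filter cells/genes, depth-normalize and log-transform.

    ``counts`` is genes × cells (raw integers).  Cells with fewer than 10
    expressed genes, more than 50% ribosomal counts, or more than 10%
    mitochondrial counts are removed; genes expressed in fewer than three
    cells are removed.  Remaining counts are scaled to a constant depth
    of 10,000 per cell and transformed as log(1 + x).
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    genes = counts.index.astype(str)
    ribo = genes.str.upper().str.startswith(RIBO_PREFIXES)
    mito = genes.str.upper().str.startswith(MITO_PREFIX)
    depth = counts.sum(axis=0)
    n_genes = (counts > 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ribo_frac = counts.loc[ribo].sum(axis=0) / depth
        mito_frac = counts.loc[mito].sum(axis=0) / depth
    good_cells = (
        (n_genes >= min_genes)
        & (ribo_frac.fillna(0) <= max_ribo_frac)
        & (mito_frac.fillna(0) <= max_mito_frac)
    )
    filtered = counts.loc[:, good_cells]
    good_genes = (filtered > 0).sum(axis=1) >= min_cells_per_gene
    filtered = filtered.loc[good_genes]
    if filtered.empty:
        raise ValueError("no cells or genes survive QC")
    depth = filtered.sum(axis=0)
    norm = filtered / depth * scale
    return np.log1p(norm)


# --------------------------------------------------------------------------
# Lineage inference


def infer_lineage(
    cell_profile: pd.Series,
    refs: pd.DataFrame,
    min_shared_genes: int = 10,
) -> tuple[str, float]:
    """Nearest reference lineage by Spearman correlation (distance 1 − ρ).

    ``refs`` is lineage × gene mean expression.  Ties are broken by
    reference row order.  Returns (lineage label, ρ).
    """
    shared = refs.columns.intersection(cell_profile.index)
    if len(shared) < min_shared_genes:
        raise ValueError(f"only {len(shared)} shared genes (< {min_shared_genes})")
    x = cell_profile[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant cell profile: Spearman undefined")
    best_label, best_rho = None, -np.inf
    for label, row in refs[shared].iterrows():
        rho = sps.spearmanr(x, row.to_numpy(dtype=float)).statistic
        if np.isnan(rho):
            continue
        if rho > best_rho:
            best_label, best_rho = label, rho
    if best_label is None:
        raise ValueError("no reference with defined correlation")
    return best_label, float(best_rho)


def infer_lineages(cells: pd.DataFrame, refs: pd.DataFrame,
                   min_shared_genes: int = 10) -> pd.DataFrame:
    """Vector version of :func:`infer_lineage` over a genes × cells matrix."""
    rows = [(bc, *infer_lineage(cells[bc], refs, min_shared_genes))
            for bc in cells.columns]
    return pd.DataFrame(rows, columns=["cell_barcode", "lineage", "rho"])


# --------------------------------------------------------------------------
# Cluster enrichment

ENRICHED = "enriched"
DEPLETED = "depleted"


def cluster_mutant_enrichment(
    mutant_cells: Iterable[str],
    cluster_of: Mapping[str, object],
    direction: str = ENRICHED,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """One-sided Fisher exact test for mutant-cell enrichment per cluster.

    Each cluster is tested against the rest of the sample with the 2×2
    table (in/out of cluster) × (mutant / not detected mutant); cells
    without a detected mutation — wild-type-looking or uncovered — form
    the "other" margin.  ``direction='depleted'`` tests under-enrichment
    (used to find normal clusters when most cells are tumor).
    """
    if direction not in (ENRICHED, DEPLETED):
        raise ValueError("direction must be 'enriched' or 'depleted'")
    mutants = set(mutant_cells)
    clusters = pd.Series(cluster_of)
    if clusters.empty:
        raise ValueError("empty cluster assignment")
    unknown = mutants - set(clusters.index)
    if unknown:
        raise ValueError(f"{len(unknown)} mutant cell(s) missing a cluster")
    total = len(clusters)
    total_mut = sum(bc in mutants for bc in clusters.index)
    rows = []
    for cl, members in clusters.groupby(clusters).groups.items():
        n_in = len(members)
        if n_in == 0:
            raise ValueError(f"cluster {cl!r} has 0 cells")
        mut_in = sum(bc in mutants for bc in members)
        table = [
            [mut_in, n_in - mut_in],
            [total_mut - mut_in, (total - n_in) - (total_mut - mut_in)],
        ]
        alt = "greater" if direction == ENRICHED else "less"
        p = sps.fisher_exact(table, alternative=alt).pvalue
        rows.append((cl, n_in, mut_in, total_mut, total, float(p)))
    df = pd.DataFrame(rows, columns=[
        "cluster", "n_cells", "n_mutant", "total_mutant", "total_cells", "p"])
    if bh_correct:
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["q"] <= alpha
    else:
        df["significant"] = df["p"] <= alpha
    return df.sort_values("p", ignore_index=True)


def mutant_cells_from_genotypes(genotypes: pd.DataFrame,
                                site: str | None = None) -> set[str]:
    """Barcodes with a detected mutation (optionally at one site)."""
    g = genotypes if site is None else genotypes[genotypes.site == site]
    return set(g.loc[g.status == MUTANT, "cell_barcode"])


def expression_normalized_mcf(
    cluster_mcf: pd.Series, cluster_mean_expr: pd.Series
) -> pd.Series:
    """Per-cluster mutant cell fraction / mean expression of the mutated gene.

    Separates genuine restriction of a mutation in expression space from
    mere restriction of the gene's expression.  Clusters where the gene
    is not expressed get NaN (the ratio is undefined there).
    """
    expr = cluster_mean_expr.reindex(cluster_mcf.index)
    out = cluster_mcf / expr.where(expr > 0)
    out.name = "expr_normalized_mcf"
    return out


# --------------------------------------------------------------------------
# Mutant-density regression


def cluster_summaries(
    expr: pd.DataFrame,
    cluster_of: Mapping[str, object],
    mutant_cells: Iterable[str],
    covariate_gene: str | None = None,
) -> pd.DataFrame:
    """Per-cluster mean expression, mutant fraction m and covariate g.

    Returns a cluster × (genes..., m, g, n_cells) frame built from a
    normalized genes × cells matrix and a cell → cluster mapping.
    """
    clusters = pd.Series({bc: cluster_of[bc] for bc in expr.columns})
    mutants = set(mutant_cells)
    rows = {}
    for cl, members in clusters.groupby(clusters).groups.items():
        sub = expr[list(members)]
        row = sub.mean(axis=1)
        row["m"] = np.mean([bc in mutants for bc in members])
        row["g"] = (row[covariate_gene] if covariate_gene is not None else np.nan)
        row["n_cells"] = len(members)
        rows[cl] = row
    return pd.DataFrame(rows).T


def density_regression(
    cluster_means: pd.DataFrame,
    m: Sequence[float],
    g: Sequence[float] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """OLS of cluster-mean expression on mutant-cell density per gene.

    ``cluster_means`` is clusters × genes; ``m`` the per-cluster mutant
    cell fraction; ``g`` an optional per-cluster covariate (mean
    expression of the mutated gene).  For each gene the model
    ``E = x + y·m (+ z·g)`` is fit and the coefficient on m is tested
    with the partial F-test of the nested model without m, followed by
    BH correction.  Selected genes have q ≤ alpha and y > 0 (positive
    association with mutant density).
    """
    import statsmodels.api as sm

    E = np.asarray(cluster_means, dtype=float)
    n_clusters, n_genes = E.shape
    m = np.asarray(m, dtype=float)
    if len(m) != n_clusters:
        raise ValueError("m must have one entry per cluster")
    if np.ptp(m) == 0:
        raise ValueError("m is constant across clusters; y is unidentifiable")
    cols = {"const": np.ones(n_clusters), "m": m}
    if g is not None:
        cols["g"] = np.asarray(g, dtype=float)
    X_full = pd.DataFrame(cols)
    X_red = X_full.drop(columns="m")
    n_params = X_full.shape[1]
    if n_clusters <= n_params:
        raise ValueError("need more clusters than regression parameters")
    rank_deficient = np.linalg.matrix_rank(X_full.to_numpy()) < n_params
    rows = []
    for j, gene in enumerate(cluster_means.columns):
        y = E[:, j]
        full = sm.OLS(y, X_full).fit()
        red = sm.OLS(y, X_red).fit()
        fstat, pval, _ = full.compare_f_test(red)
        if np.isnan(pval):  # zero-residual fits: perfect fit or constant gene
            pval = 0.0 if abs(full.params["m"]) > 1e-12 else 1.0
        rows.append((
            gene,
            full.params["const"],
            full.params["m"],
            full.params.get("g", np.nan),
            float(fstat) if np.isfinite(fstat) else np.inf,
            float(pval),
        ))
    df = pd.DataFrame(rows, columns=["gene", "x", "y", "z", "F", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["selected"] = (df["q"] <= alpha) & (df["y"] > 0)
    df["rank_deficient"] = rank_deficient
    return df


# --------------------------------------------------------------------------
# Wilcoxon signature (mutant-rich vs mutant-poor clusters)


def wilcoxon_signature(
    expr: pd.DataFrame,
    cluster_of: Mapping[str, object],
    cluster_mutation_fraction: Mapping[object, float],
    rich_threshold: float = 0.10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene rank-sum test of mutant-rich vs remaining clusters' cells.

    Clusters with mutation fraction strictly above ``rich_threshold``
    form the rich group (a cluster at exactly 10% is non-rich); the test
    pools cells by the group of their cluster.
    """
    rich_clusters = {cl for cl, f in cluster_mutation_fraction.items()
                     if f > rich_threshold}
    rich_cells = [bc for bc in expr.columns if cluster_of[bc] in rich_clusters]
    poor_cells = [bc for bc in expr.columns if cluster_of[bc] not in rich_clusters]
    if not rich_cells or not poor_cells:
        raise ValueError(
            f"both groups must be nonempty at rich threshold > {rich_threshold}")
    a = expr[rich_cells].to_numpy(dtype=float)
    b = expr[poor_cells].to_numpy(dtype=float)
    stat, p = sps.mannwhitneyu(a, b, axis=1, alternative="two-sided")
    df = pd.DataFrame({"gene": expr.index, "U": stat, "p": p})
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] <= alpha
    return df


# --------------------------------------------------------------------------
# Correlation screen and gene-set overlap


def correlation_screen(
    bulk: pd.DataFrame,
    anchor_gene: str,
    q_cut: float = 0.001,
) -> pd.DataFrame:
    """Genes correlated with an anchor gene across bulk samples.

    ``bulk`` is genes × samples.  Per gene: Pearson r with the anchor,
    two-sided p from the exact t transform, BH q; genes (other than the
    anchor itself) with q < q_cut are flagged ``in_set`` regardless of
    sign.
    """
    if anchor_gene not in bulk.index:
        raise ValueError(f"anchor gene {anchor_gene!r} not in matrix")
    n = bulk.shape[1]
    if n < 10:
        raise ValueError("need at least 10 samples")
    x = bulk.loc[anchor_gene].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant anchor gene")
    Y = bulk.to_numpy(dtype=float)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum() * (Yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ xc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(np.isnan(r), 1.0, p)
    df = pd.DataFrame({"gene": bulk.index, "r": r, "p": p})
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["in_set"] = (df["q"] < q_cut) & (df["gene"] != anchor_gene)
    return df


def geneset_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> tuple[int, float]:
    """Overlap size and upper-tail hypergeometric p-value.

    p = P(overlap ≥ observed) when |B| genes are drawn from the universe
    uniformly without replacement, given |A| marked genes.
    """
    universe = set(universe)
    A, B = set(set_a), set(set_b)
    if not A <= universe or not B <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    k = len(A & B)
    p = float(sps.hypergeom.sf(k - 1, len(universe), len(A), len(B)))
    return k, p


# --------------------------------------------------------------------------


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone q-values, q >= p)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
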