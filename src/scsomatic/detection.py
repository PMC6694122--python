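"""Detection-probability model for expressed heterozygous mutations.

The expected number of detected mutant cells when sequencing *n* cells is

    E = n · a · ( f · [1 − (1 − c·t)^r] + (1 − f) · e )
      ≈ n · a · f · r · c · t  +  n · a · (1 − f) · e,

where *a* is the tumor-cell fraction, *f* twice the bulk-DNA variant
allele frequency (the fraction of tumor cells carrying the heterozygous
mutation), *t* the relative expression of the gene (counts per million /
10⁶, i.e. the probability that one UMI comes from the gene), *r* the
average UMIs per cell, *c* the fraction of the gene's UMIs covering the
variant position, and *e* the site-specific false-positive rate.  The
bracketed term is the chance that at least one of a cell's ~r·t gene
molecules covers the site; the approximation holds when c·t·r is small.

Although often read as a probability, E is an expected count and can
exceed 1; ``prob_at_least_one`` gives the corresponding probability that
at least one mutant cell is detected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class DetectionParams:
    """Inputs of the detection model (see module docstring for symbols)."""

    n: int  # total cells sequenced
    a: float  # tumor-cell fraction
    f: float  # twice the bulk-DNA VAF (mutant fraction of tumor cells)
    t: float  # relative gene expression as a fraction (CPM / 1e6)
    r: float  # average UMIs per cell
    c: float  # fraction of the gene's UMIs covering the variant position
    e: float = 0.0  # site-specific false-positive rate

    def __post_init__(self):
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 0):
            raise ValueError("n must be a non-negative integer")
        for name in ("a", "f", "t", "c"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1] (got {v})")
        if self.r < 0:
            raise ValueError("r must be >= 0")
        if not 0.0 <= self.e < 1.0:
            raise ValueError("e must lie in [0, 1)")

    @classmethod
    def from_cpm(cls, cpm: float, **kwargs) -> "DetectionParams":
        """Build parameters giving the gene's expression in CPM."""
        return cls(t=cpm / 1e6, **kwargs)


def per_cell_detection_prob(p: DetectionParams) -> float:
    """Probability that one sequenced cell yields a (true or false) mutant call."""
    # 1 - (1 - ct)^r via log1p for numerical stability at small c·t
    ct = p.c * p.t
    if ct >= 1.0:
        covered = 1.0
    else:
        covered = -math.expm1(p.r * math.log1p(-ct))
    return p.a * (p.f * covered + (1.0 - p.f) * p.e)


def expected_mutant_cells(p: DetectionParams) -> float:
    """Exact expected number of detected mutant cells, n·a·(f[1−(1−ct)^r]+(1−f)e)."""
    return p.n * per_cell_detection_prob(p)


def approx_mutant_cells(p: DetectionParams) -> float:
    """First-order approximation n·a·f·r·c·t + n·a·(1−f)·e (≥ the exact form)."""
    return p.n * p.a * (p.f * p.r * p.c * p.t + (1.0 - p.f) * p.e)


def prob_at_least_one(p: DetectionParams) -> float:
    """P(detect ≥ 1 mutant cell) = 1 − (1 − q)^n with q the per-cell term."""
    q = per_cell_detection_prob(p)
    if q >= 1.0:
        return 1.0
    return -math.expm1(p.n * math.log1p(-q))


def cells_required(target_cells: float, p: DetectionParams) -> int:
    """Smallest n with expected_mutant_cells >= target_cells (design inverse).

    The expectation is linear in n, so this is ceil(target / per-cell term);
    ``p.n`` is ignored.
    """
    if target_cells <= 0:
        return 0
    q = per_cell_detection_prob(p)
    if q <= 0.0:
        raise ValueError("per-cell detection probability is 0; infeasible target")
    return math.ceil(target_cells / q - 1e-12)


def monte_carlo_expected(
    p: DetectionParams, replicates: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Simulate the detection process; returns (mean detected cells, SE).

    Per replicate: each of n cells is tumor with probability a; a tumor
    cell carries the mutation with probability f, in which case its UMI
    count is Poisson(r) and each UMI covers the site with probability c·t
    (detection iff >= 1 covering UMI); a non-carrier tumor cell is
    miscalled mutant with probability e.  Using a Poisson UMI count where
    the closed form fixes r is a deliberate, documented difference; it is
    negligible for large r and small c·t.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    ct = min(p.c * p.t, 1.0)
    n_tumor = rng.binomial(p.n, p.a, size=replicates)
    n_carrier = rng.binomial(n_tumor, p.f)
    n_noncarrier = n_tumor - n_carrier
    # carriers: detected iff Poisson(r) thinned by ct is >= 1, i.e. with
    # per-cell probability 1 - exp(-r*ct) conditional on nothing -- but we
    # draw the per-cell UMI counts explicitly to keep this a genuine
    # simulation of the generative story rather than the closed form.
    total_carriers = int(n_carrier.sum())
    umis = rng.poisson(p.r, size=total_carriers)
    if ct < 1.0:
        p_detect = -np.expm1(umis * math.log1p(-ct))  # 1 - (1-ct)^k
    else:
        p_detect = (umis >= 1).astype(float)
    detected_flags = rng.random(total_carriers) < p_detect
    # split the flat carrier axis back into replicates
    bounds = np.cumsum(n_carrier)[:-1]
    det_carriers = np.array(
        [seg.sum() for seg in np.split(detected_flags, bounds)], dtype=float
    )
    det_errors = rng.binomial(n_noncarrier, p.e)
    counts = det_carriers + det_errors
    mean = float(counts.mean())
    se = float(counts.std(ddof=1) / math.sqrt(replicates)) if replicates > 1 else 0.0
    return mean, se


def with_n(p: DetectionParams, n: int) -> DetectionParams:
    return replace(p, n=n)
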