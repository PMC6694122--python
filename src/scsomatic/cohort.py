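"""Published summary tallies from a five-sample AML scRNA-seq cohort.

These are the printed per-sample counts from the study that motivated
this tool: five cryopreserved AML bone-marrow samples profiled with the
droplet 5' workflow alongside enhanced whole-genome sequencing.  They
serve as worked examples — the package's tally and ratio arithmetic,
applied to these inputs, must reproduce the published percentages.

One known inconsistency in the source tables is resolved here: the
overview table prints 386 total mutant cells for sample 809653 while the
multi-mutation table and the quoted range (396–8200 mutant cells per
sample) use 396; 396 is internally consistent (386 cells with one
mutation + 10 with two), so it is stored as the total.
"""

from __future__ import annotations

import statistics

SAMPLES = ("508084", "548327", "721214", "782328", "809653")

#: total cells per sample
N_CELLS = {"508084": 14_964, "548327": 11_620, "721214": 20_474,
           "782328": 21_731, "809653": 21_038}

#: somatic variants found by bulk DNA sequencing
N_WGS_VARIANTS = {"508084": 19, "548327": 13, "721214": 41, "782328": 31,
                  "809653": 28}

#: of those, expressed in bulk RNA-seq
N_EXPRESSED_VARIANTS = {"508084": 10, "548327": 5, "721214": 18,
                        "782328": 7, "809653": 8}

#: of those, detected in at least one cell in the scRNA-seq data
N_SCRNA_VARIANTS = {"508084": 8, "548327": 7, "721214": 17, "782328": 12,
                    "809653": 8}

#: cells with at least one detected mutation
N_MUTANT_CELLS = {"508084": 669, "548327": 6042, "721214": 8200,
                  "782328": 3354, "809653": 396}

#: median mutant cells per variant, per sample
MEDIAN_MUTANT_CELLS_PER_VARIANT = {"508084": 32, "548327": 48, "721214": 30,
                                   "782328": 111, "809653": 21.5}

#: mutant cells carrying exactly k distinct detected mutations
MULTI_MUTATION_COUNTS = {
    "508084": {1: 658, 2: 11},
    "548327": {1: 5290, 2: 734, 3: 18},
    "721214": {1: 7702, 2: 477, 3: 20, 4: 1},
    "782328": {1: 3176, 2: 171, 3: 7},
    "809653": {1: 386, 2: 10},
}

#: discordant / total UMI groups observed in sample 782328
DISCORDANT_UMI_GROUPS = (4, 6218)


def detection_ratio(sample: str) -> float:
    """scRNA-detected / bulk-expressed variant count for one sample."""
    return N_SCRNA_VARIANTS[sample] / N_EXPRESSED_VARIANTS[sample]


def mean_detection_ratio() -> float:
    """Cross-sample mean of the per-sample detection ratios."""
    return statistics.mean(detection_ratio(s) for s in SAMPLES)


def mean_median_mutant_cells() -> float:
    """Mean over samples of the per-sample median mutant cells per variant."""
    return statistics.mean(MEDIAN_MUTANT_CELLS_PER_VARIANT[s] for s in SAMPLES)


def mutant_cell_percentages() -> dict[str, float]:
    """Mutant cells as a percentage of all cells, per sample."""
    return {s: 100.0 * N_MUTANT_CELLS[s] / N_CELLS[s] for s in SAMPLES}


def mean_mutant_cells() -> float:
    """Cross-sample mean number of mutant cells."""
    return statistics.mean(N_MUTANT_CELLS[s] for s in SAMPLES)
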