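"""Published summary statistics from the long-term arctic fox monitoring data.

These are the printed group-level numbers from two decades of den monitoring
of the Scandinavian arctic fox rescue system (Helagsfjallen): mean litter
sizes per breeding-pair ancestry combination, mean life span and lifetime
reproductive success (LRS) per individual ancestry class, and the LoF
gene-pool counts of the resequenced native and immigrant-descendant
(hybrid) genomes. They serve as worked-example inputs for the contrast and
gene-pool arithmetic; they are data, not expected test outputs.
"""

from __future__ import annotations

# mean litter size (cubs) per pair ancestry combination, with litter counts
PAIR_LITTER_MEANS: dict[str, float] = {
    "native_x_native": 6.30,
    "native_x_immigrant": 11.17,
    "native_x_immigrantF1F4": 5.14,
    "immigrantF1F4_x_immigrantF1F4": 6.05,
}
PAIR_LITTER_N: dict[str, int] = {
    "native_x_native": 37,
    "native_x_immigrant": 6,
    "native_x_immigrantF1F4": 59,
    "immigrantF1F4_x_immigrantF1F4": 19,
}

# mean life span (years) per individual ancestry class (adults only)
LIFESPAN_MEANS: dict[str, float] = {
    "native": 3.8,
    "F1": 4.8,
    "F2+F3": 3.2,
}

# mean lifetime reproductive success (cubs) per individual ancestry class
LRS_MEANS: dict[str, float] = {
    "native": 7.60,
    "F1": 12.19,
    "F2+F3": 6.94,
}

ANCESTRY_N: dict[str, int] = {"native": 30, "F1": 21, "F2+F3": 34}

# number of LoF variants in each gene pool of the resequenced panel
LOF_GENE_POOL_COUNTS: dict[str, int] = {"native": 1168, "hybrid": 1220}
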