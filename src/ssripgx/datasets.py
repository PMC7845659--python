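"""Published reference summary statistics bundled for validation and demos.

``htr2a_summary()`` returns the published two-cohort single-marker summary
for the *HTR2A* region (serotonin receptor 2A, chromosome 13q14.2) from a
two-centre Han Chinese SSRI antidepressant-response study: per-cohort minor
allele frequency, odds ratio and p-value for the remission and response
phenotypes, together with the printed pooled (mega) and combined (meta)
p-values.  These printed numbers serve as fixed inputs for exercising the
p-value combination and threshold-classification machinery; they are not
recomputed from genotypes.

``PUBLISHED_RATES`` carries the study's printed outcome counts
(count, denominator) for rate computations.
"""

from __future__ import annotations

import pandas as pd

# columns: snp, position, phenotype, maf/or/p per cohort, mega maf/or/p, meta p
_ROWS = [
    # remission (week-8 HRSD total <= 7), coded binary
    ("rs7333412", 47403360, "remitted", 0.1779, 1.91, 6.1e-3, 0.1518, 2.00, 5.2e-2, 0.1659, 1.88, 9.0e-4, 2.9e-3),
    ("rs7324017", 47406845, "remitted", 0.1779, 1.91, 6.1e-3, 0.1488, 2.05, 4.4e-2, 0.1647, 1.91, 7.1e-4, 2.5e-3),
    ("rs3803189", 47408570, "remitted", 0.1779, 1.91, 6.1e-3, 0.1467, 2.10, 3.9e-2, 0.1639, 1.93, 5.9e-4, 2.2e-3),
    ("rs3125", 47408851, "remitted", 0.1779, 1.91, 6.1e-3, 0.1467, 2.10, 3.9e-2, 0.1639, 1.93, 5.9e-4, 2.2e-3),
    ("rs7322347", 47410103, "remitted", 0.2321, 2.19, 5.3e-4, 0.2024, 2.10, 2.6e-2, 0.2190, 2.04, 6.9e-4, 1.7e-4),
    ("chr13:47410325:D", 47410325, "remitted", 0.1844, 1.91, 6.7e-3, 0.1509, 2.16, 3.5e-2, 0.1695, 1.95, 5.8e-4, 2.2e-3),
    ("rs1923882", 47411661, "remitted", 0.1786, 1.90, 6.8e-3, 0.1488, 2.05, 4.4e-2, 0.1651, 1.90, 7.7e-4, 2.7e-3),
    ("rs55948462", 47412075, "remitted", 0.1786, 1.90, 6.8e-3, 0.1467, 2.10, 3.9e-2, 0.1643, 1.92, 6.4e-4, 2.4e-3),
    ("rs56005991", 47412741, "remitted", 0.1873, 2.18, 1.1e-3, 0.1647, 1.89, 6.3e-2, 0.1775, 2.01, 2.1e-4, 7.4e-4),
    ("rs977003", 47415001, "remitted", 0.2312, 2.21, 4.5e-4, 0.2054, 2.01, 3.3e-2, 0.2209, 2.00, 8.8e-5, 1.8e-4),
    ("rs61948314", 47415383, "remitted", 0.1714, 1.95, 5.9e-3, 0.1402, 2.10, 4.2e-2, 0.1575, 1.98, 4.9e-4, 2.3e-3),
    ("rs75907607", 47416042, "remitted", 0.1714, 1.95, 5.9e-3, 0.1402, 2.10, 4.2e-2, 0.1575, 1.98, 4.9e-4, 2.3e-3),
    ("rs17068986", 47416386, "remitted", 0.4822, 0.51, 5.2e-4, 0.4940, 0.73, 2.8e-1, 0.4883, 0.59, 6.0e-4, 1.2e-3),
    ("rs76703096", 47416712, "remitted", 0.1390, 1.84, 2.5e-2, 0.1180, 1.97, 8.5e-2, 0.1296, 1.86, 4.1e-3, 1.5e-2),
    # response (>= 50% HRSD reduction at week 4), coded binary
    ("rs7333412", 47403360, "response", 0.1779, 1.72, 2.0e-2, 0.1518, 1.86, 5.6e-2, 0.1659, 1.72, 3.7e-3, 8.7e-3),
    ("rs3803189", 47408570, "response", 0.1779, 1.72, 2.0e-2, 0.1467, 1.80, 7.1e-2, 0.1639, 1.71, 4.4e-3, 1.1e-2),
    ("rs3125", 47408851, "response", 0.1779, 1.72, 2.0e-2, 0.1467, 1.80, 7.1e-2, 0.1639, 1.71, 4.4e-3, 1.1e-2),
    ("chr13:47410325:D", 47410325, "response", 0.1844, 1.69, 2.6e-2, 0.1509, 1.97, 4.3e-2, 0.1695, 1.74, 3.6e-3, 8.8e-3),
    ("rs55948462", 47412075, "response", 0.1786, 1.71, 2.2e-2, 0.1467, 1.80, 7.1e-2, 0.1643, 1.70, 4.7e-3, 1.2e-2),
    ("rs61948314", 47415383, "response", 0.1714, 1.75, 1.9e-2, 0.1402, 1.88, 5.9e-2, 0.1575, 1.77, 3.1e-3, 8.9e-3),
    ("rs75907607", 47416042, "response", 0.1714, 1.75, 1.9e-2, 0.1402, 1.88, 5.9e-2, 0.1575, 1.77, 3.1e-3, 8.9e-3),
    ("rs17068986", 47416386, "response", 0.4822, 0.54, 1.4e-3, 0.4940, 0.78, 3.0e-1, 0.4883, 0.62, 1.1e-3, 3.3e-3),
]

_COLUMNS = ["snp", "position", "phenotype",
            "maf_a", "or_a", "p_a", "maf_b", "or_b", "p_b",
            "maf_mega", "or_mega", "mega_p", "meta_p"]


def htr2a_summary(phenotype: str | None = None) -> pd.DataFrame:
    """Published *HTR2A*-region single-marker summary statistics.

    Cohort "a" is the larger centre (253 analysed subjects), cohort "b" the
    smaller (175).  Optionally filter to one phenotype ("remitted" or
    "response").
    """
    df = pd.DataFrame(_ROWS, columns=_COLUMNS)
    if phenotype is not None:
        df = df[df["phenotype"] == phenotype].reset_index(drop=True)
    return df


#: printed outcome counts of the source study: name -> (count, denominator)
PUBLISHED_RATES = {
    "remission_week2": (26, 428),
    "remission_week4": (57, 428),
    "remission_week8": (140, 428),
    "response_week4": (163, 421),
    "women": (300, 421),
    "stem_responders": (373, 421),
    "stem_nonresponders": (48, 421),
}
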