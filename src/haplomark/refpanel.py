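"""Bundled published summary of BADH2 gene-haplotype diversity in rice.

Two reference summaries ship with the package and drive fixtures, examples
and the acceptance report:

* a global diversity panel of 2,932 *O. sativa* accessions — per-haplotype
  subpopulation counts and nine-site consensus allele strings;
* a 369-line U.S. breeding panel genotyped with eight of those sites,
  with replicated 2AP (aroma compound) concentration summaries for a
  39-line phenotyped subset.

Marker positions are 1-based IRGSP v1 coordinates on rice chromosome 8.
``SNP1`` lies upstream of the gene and is diagnostic of the aromatic
haplotype (group 6); ``SNP2``–``SNP9`` are gene-internal.
"""

from __future__ import annotations

import pandas as pd

from .model import GenotypeMatrix, matrix_from_vectors

CHROM = "Chr8"

#: marker label -> 1-based position (assay order, not genomic order)
MARKER_POSITIONS = {
    "SNP1": 20374951,
    "SNP2": 20381787,
    "SNP3": 20382161,
    "SNP4": 20384350,
    "SNP5": 20382286,
    "SNP6": 20380447,
    "SNP7": 20381308,
    "SNP8": 20380886,
    "SNP9": 20382480,
}

MARKER_ORDER = [f"SNP{i}" for i in range(1, 10)]

#: nominal gene interval used for flank-distance bookkeeping (1-based
#: inclusive); contains SNP2..SNP9, with SNP1 in the upstream flank.
GENE_INTERVAL = (CHROM, 20380000, 20385000)

SUBPOPULATIONS = [
    "aus",
    "indica",
    "admix",
    "aromatic",
    "temperate japonica",
    "tropical japonica",
    "japonica admixture",
]

#: columns of the Japonica varietal group within :data:`SUBPOPULATIONS`
JAPONICA_GROUP = ["aromatic", "temperate japonica", "tropical japonica", "japonica admixture"]

#: haplotype group -> counts per subpopulation (global 2,932-accession panel)
GLOBAL_COUNTS = {
    "1": [1, 749, 12, 0, 1, 121, 8],
    "2": [2, 148, 19, 26, 215, 281, 64],
    "3": [0, 201, 1, 0, 1, 0, 0],
    "4": [9, 183, 5, 0, 0, 0, 0],
    "5": [1, 186, 5, 2, 0, 1, 0],
    "6": [0, 65, 9, 38, 3, 53, 3],
    "7": [97, 11, 6, 0, 0, 0, 0],
    "8": [0, 89, 2, 1, 0, 2, 0],
    "9": [63, 13, 6, 3, 0, 0, 0],
    "10": [1, 39, 6, 0, 2, 4, 0],
    "11": [3, 22, 6, 0, 0, 0, 0],
    "R": [22, 42, 6, 2, 0, 2, 0],
    "U": [2, 41, 16, 3, 2, 3, 2],
}

#: haplotype group -> consensus allele string over SNP1..SNP9 (assay order)
GLOBAL_CONSENSUS = {
    "1": "GAGGAGGTC",
    "2": "GTAGACGTC",
    "3": "GAGAACCTC",
    "4": "GAGGAGCTC",
    "5": "GTGGACCTC",
    "6": "TTAGACCTC",
    "7": "GAGGACCTC",
    "8": "GAGGGGGTC",
    "9": "GAGGACCTC",
    "10": "GAGGAGGTT",
    "11": "GAGGAGCCC",
}

AROMATIC_GROUP = "6"

#: U.S. panel: group label -> (n lines, n phenotyped, 2AP min, 2AP max,
#: 2AP mean, 2AP SE, allele code over SNP1..SNP8)
US_PANEL = {
    "1": (181, 5, 0.0, 0.0, 0.0, 0.0, "GAGGAGGT"),
    "2": (134, 9, 0.0, 0.079, 0.009, 0.005, "GTAGACCT"),
    "3": (11, 2, 0.0, 0.0, 0.0, 0.0, "GAGAACCT"),
    "5": (5, 3, 0.0, 0.001, 0.0002, 0.0002, "GTGGACCT"),
    "6": (27, 17, 0.356, 3.165, 1.30, 0.058, "TTAGACCT"),
    "7/9": (11, 3, 0.0, 0.009, 0.003, 0.002, "GAGGACCT"),
}

US_PANEL_TOTAL = 369

#: validation experiment geometry for the diagnostic-marker assay
VALIDATION_LINES = 351
VALIDATION_JOBS = 3
VALIDATION_FAILED = 7
VALIDATION_AMBIGUOUS = 4

#: observed 2AP concentration ranges (ppm) for deletion carriers /
#: non-carriers, used as simulation defaults
CARRIER_2AP_RANGE = (0.356, 3.165)
NONCARRIER_2AP_RANGE = (0.0, 0.079)


def global_counts_frame() -> pd.DataFrame:
    """Group x subpopulation counts of the global panel, with margins."""
    df = pd.DataFrame.from_dict(GLOBAL_COUNTS, orient="index", columns=SUBPOPULATIONS)
    df["Total"] = df.sum(axis=1)
    df.loc["Total"] = df.sum(axis=0)
    return df


def consensus_frame() -> pd.DataFrame:
    """Consensus alleles of the 11 global haplotype groups, one column per
    site ID, columns in genomic order."""
    labels = sorted(MARKER_POSITIONS, key=MARKER_POSITIONS.get)
    data = {
        f"{CHROM}:{MARKER_POSITIONS[m]}": [
            GLOBAL_CONSENSUS[g][MARKER_ORDER.index(m)] for g in GLOBAL_CONSENSUS
        ]
        for m in labels
    }
    return pd.DataFrame(data, index=list(GLOBAL_CONSENSUS))


def consensus_genotypes() -> GenotypeMatrix:
    """The 11 consensus vectors as a small genotype matrix (one pseudo-sample
    per haplotype group, named ``Hap1`` .. ``Hap11``)."""
    positions = [MARKER_POSITIONS[m] for m in MARKER_ORDER]
    vectors = {f"Hap{g}": v for g, v in GLOBAL_CONSENSUS.items()}
    return matrix_from_vectors(vectors, positions, chrom=CHROM)


def marker_site_id(label: str) -> str:
    return f"{CHROM}:{MARKER_POSITIONS[label]}"
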