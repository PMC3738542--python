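"""Reported measurements from the three-strain batch study this package models.

The comparative high-glucose batch cultivation of *E. coli* HMS174, RV308
and BL21 (three replicate runs per strain) reported per-run average growth
rates, end-of-run cell dry mass and maximum acetate, plus transcript/protein
contrast values for identified proteins.  Those printed values serve as
worked-example inputs for the replicate-summary, yield and integration
operations; the package recomputes everything else.
"""

from __future__ import annotations

import pandas as pd

#: Per-run process parameters: average growth rate (1/h), end CDM (g/L),
#: maximum acetate in the supernatant (g/L).  One row per replicate run.
CULTIVATION_RUNS = pd.DataFrame(
    [
        ("HMS1", "HMS174", 0.47, 13.33, 6.25),
        ("HMS2", "HMS174", 0.40, 14.41, 6.00),
        ("HMS3", "HMS174", 0.43, 13.43, 5.54),
        ("RV1", "RV308", 0.50, 15.16, 6.01),
        ("RV2", "RV308", 0.47, 14.88, 4.70),
        ("RV3", "RV308", 0.46, 17.49, 5.89),
        ("BL1", "BL21", 0.73, 17.74, 1.37),
        ("BL2", "BL21", 0.74, 15.60, 1.18),
        ("BL3", "BL21", 0.73, 17.90, 1.34),
    ],
    columns=["run", "strain", "growth_rate", "end_cdm", "max_acetate"],
)

#: Initial glucose of every batch (g/L, anhydrous basis).
INITIAL_GLUCOSE = 40.0

#: Whole-study mean final CDM (g/L) and accumulated acetate (g/L) per strain,
#: as quoted in the study prose.
PROSE_MEANS = {
    "HMS174": {"final_cdm": 13.72, "acetate": 5.93},
    "RV308": {"final_cdm": 15.84, "acetate": 5.53},
    "BL21": {"final_cdm": 17.41, "acetate": 1.30},
}

#: Acetate concentrations (g/L) the study plugged into its yield correction:
#: "approximately 6 g/L" for both K-12 strains and 1.3 g/L for the B strain.
YIELD_CORRECTION_ACETATE = {"HMS174": 6.0, "RV308": 6.0, "BL21": 1.3}

#: Selected identified proteins with DIGE signed folds and gene log2-ratio
#: differences per strain pair (protein_<pair>, gene_<pair>); NaN = the gene
#: value was not measurable.
PROTEIN_GENE_CONTRASTS = pd.DataFrame(
    [
        ("AceA", "aceA", -6.24, -1.05, 5.95, -3.96, 0.08, 4.04),
        ("GatD", "gatD", 9.69, 11.44, 1.18, 3.56, 4.09, 0.53),
        ("MalE", "malE", 9.69, 22.89, 2.36, 4.44, 5.27, 0.83),
        ("CysP", "cysP", 15.60, 1.08, -2.14, 0.97, 2.30, 1.33),
        ("ProS", "proS", 2.97, 2.35, -1.26, 0.00, -0.49, -0.50),
    ],
    columns=[
        "protein",
        "gene",
        "protein_BL21-HMS174",
        "protein_BL21-RV308",
        "protein_HMS174-RV308",
        "gene_BL21-HMS174",
        "gene_BL21-RV308",
        "gene_HMS174-RV308",
    ],
)
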