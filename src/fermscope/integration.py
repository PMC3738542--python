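"""Transcript-protein integration: pairwise strain contrasts and concordance.

Gene-side contrasts between strains are differences of reference-relative
log2 ratios (M_X - M_Y), which satisfy the cycle identity
(X-Y) = (X-Z) - (Y-Z) exactly.  Protein-side contrasts are DIGE signed fold
changes.  A feature is called concordant for a pair when both levels move
the same way; a flat transcript with a large protein fold is discordant.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import DesignError

#: Calls emitted by :func:`concordance_call`.
CONCORDANT, DISCORDANT, GENE_NA, PROTEIN_NA = (
    "concordant",
    "discordant",
    "gene-NA",
    "protein-NA",
)

DEFAULT_GENE_THRESHOLD = 0.5  # log2 units below which a transcript counts as flat
LARGE_PROTEIN_FOLD = 2.0  # |signed fold| above which a protein counts as changed


def pairwise_gene_contrast(
    m_by_strain: pd.DataFrame, pairs: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Per-gene pairwise differences of reference-relative log2 ratios.

    ``m_by_strain`` is indexed by gene with one column per strain.  Returns
    a long frame (gene, pair, gene_diff); a strain's missing M yields NaN
    for its pairs.
    """
    strains = list(m_by_strain.columns)
    if pairs is None:
        pairs = list(combinations(strains, 2))
    rows = []
    for a, b in pairs:
        if a not in strains or b not in strains:
            raise DesignError(f"pair ({a}, {b}) references unknown strains")
        rows.append(
            pd.DataFrame(
                {
                    "gene": m_by_strain.index,
                    "pair": f"{a}-{b}",
                    "gene_diff": (m_by_strain[a] - m_by_strain[b]).to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def concordance_call(
    gene_diff: float,
    protein_fold: float,
    gene_threshold: float = DEFAULT_GENE_THRESHOLD,
    protein_threshold: float = LARGE_PROTEIN_FOLD,
) -> str:
    """Classify one feature/pair as concordant, discordant or NA.

    Rules (a declared convention; the underlying assay reports examples,
    not a rule): missing values give the NA calls; when the transcript
    moved (|gene_diff| >= gene_threshold) the call follows sign agreement
    with the protein fold; when the transcript is flat, a protein fold
    beyond ``protein_threshold`` is discordant and a small one concordant
    (both levels unchanged).
    """
    if protein_fold is None or (isinstance(protein_fold, float) and np.isnan(protein_fold)) or protein_fold == 0:
        return PROTEIN_NA
    if gene_diff is None or (isinstance(gene_diff, float) and np.isnan(gene_diff)):
        return GENE_NA
    large_protein = abs(protein_fold) > protein_threshold
    if abs(gene_diff) >= gene_threshold:
        same_sign = (gene_diff > 0) == (protein_fold > 0)
        return CONCORDANT if same_sign else DISCORDANT
    return DISCORDANT if large_protein else CONCORDANT


@dataclass
class ContrastTable:
    """Joined per-feature protein and gene contrasts with concordance calls."""

    table: pd.DataFrame  # feature, gene, pair, protein_fold, gene_diff, call


def integrate_contrasts(
    gene_m: pd.DataFrame,
    protein_contrasts: pd.DataFrame,
    spot_gene_map: pd.DataFrame,
    gene_threshold: float = DEFAULT_GENE_THRESHOLD,
) -> ContrastTable:
    """Build the integrated contrast table.

    ``gene_m``: genes x strains reference-relative log2 ratios.
    ``protein_contrasts``: output of :func:`fermscope.proteome.dige_contrasts`.
    ``spot_gene_map``: columns spot_id, gene — spots mapping to several
    proteins carry several rows and produce one output row per constituent.
    """
    req = {"spot_id", "gene"}
    if not req <= set(spot_gene_map.columns):
        raise DesignError("spot_gene_map needs columns spot_id and gene")
    pairs = sorted(protein_contrasts["pair"].unique())
    pair_tuples = [tuple(p.split("-", 1)) for p in pairs]
    gene_diffs = pairwise_gene_contrast(
        gene_m, pairs=[t for t in pair_tuples if set(t) <= set(gene_m.columns)]
    )
    merged = (
        protein_contrasts.merge(spot_gene_map, on="spot_id", how="left")
        .merge(gene_diffs, on=["gene", "pair"], how="left")
    )
    merged["call"] = [
        concordance_call(g, f, gene_threshold=gene_threshold)
        for g, f in zip(merged["gene_diff"], merged["signed_ratio"])
    ]
    merged = merged.rename(columns={"signed_ratio": "protein_fold"})
    cols = ["spot_id", "gene", "pair", "protein_fold", "p", "gene_diff", "call"]
    return ContrastTable(table=merged[[c for c in cols if c in merged.columns]])
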