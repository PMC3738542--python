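"""DIGE internal-standard ratio analysis.

Spot volumes are standardized against the Cy2 internal standard run on every
gel, group means per strain are compared as signed fold changes (ratios
below 1 reported as the negative reciprocal, so magnitudes are symmetric
about ±1), and spots are called altered when the absolute signed ratio
exceeds 2.0 with a Student's t-test p-value below 0.01 (both strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, DomainError

RATIO_THRESHOLD = 2.0
P_THRESHOLD = 0.01


def standardize_abundance(gels: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-spot standardized abundance (sample volume / Cy2 volume).

    Input frames use the DIGE TSV dialect (one row per spot per gel with
    Cy2/Cy3/Cy5 volumes and sample labels).  Returns a long frame with
    columns spot_id, gel_id, ph_range, sample, abundance.  Spots with a
    non-positive Cy2 volume are dropped with a warning; a missing sample
    channel is simply absent, never zero.
    """
    rows = []
    dropped = 0
    for gel in gels:
        cy2 = gel["cy2_vol"].to_numpy(float)
        bad = ~(cy2 > 0)
        if bad.any():
            dropped += int(bad.sum())
        usable = gel[~bad]
        for dye in ("cy3", "cy5"):
            sample = usable[f"sample_{dye}"]
            present = sample.astype(str).str.len() > 0
            vol = usable[f"{dye}_vol"].to_numpy(float)
            ok = present & pd.notna(usable[f"{dye}_vol"])
            sub = usable[ok]
            if sub.empty:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "spot_id": sub["spot_id"].to_numpy(),
                        "gel_id": sub["gel_id"].to_numpy(),
                        "ph_range": sub["ph_range"].to_numpy(),
                        "sample": sub[f"sample_{dye}"].to_numpy(),
                        "abundance": sub[f"{dye}_vol"].to_numpy(float)
                        / sub["cy2_vol"].to_numpy(float),
                    }
                )
            )
    if dropped:
        warnings.warn(f"{dropped} spot/gel records with non-positive Cy2 volume dropped")
    if not rows:
        raise DesignError("no usable sample channels in the gel set")
    return pd.concat(rows, ignore_index=True)


def signed_fold_change(mean_a: float, mean_b: float) -> float:
    """DeCyder-style signed fold: r if r >= 1 else -1/r, with r = a/b."""
    if mean_a <= 0 or mean_b <= 0:
        raise DomainError("group means must be positive")
    r = mean_a / mean_b
    return r if r >= 1.0 else -1.0 / r


@dataclass(frozen=True)
class ProteinContrast:
    """One spot's contrast between two strains."""

    spot_id: str
    pair: str
    signed_ratio: float
    p: float
    n_a: int
    n_b: int
    ph_range: str
    altered: bool


def dige_contrasts(
    abundances: pd.DataFrame,
    sample_strain: dict[str, str],
    pairs: list[tuple[str, str]] | None = None,
    test: str = "student",
    ratio_threshold: float = RATIO_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Pairwise strain contrasts per spot with alteration calls.

    Ratios come from group means of standardized abundance; p-values from a
    two-sided two-sample t-test: ``test`` one of ``student`` (equal
    variance, default), ``welch`` or ``paired`` (requires equal replicate
    counts in gel order).  Spots with fewer than 2 replicates in either
    group are skipped with a warning.
    """
    if test not in {"student", "welch", "paired"}:
        raise DesignError(f"unknown test {test!r}")
    ab = abundances.copy()
    ab["strain"] = ab["sample"].map(sample_strain)
    if ab["strain"].isna().any():
        missing = sorted(ab.loc[ab["strain"].isna(), "sample"].unique())
        raise DesignError(f"samples without a strain assignment: {missing}")
    strains = sorted(ab["strain"].unique())
    if pairs is None:
        pairs = list(combinations(strains, 2))
    rows = []
    skipped = 0
    for spot_id, spot in ab.groupby("spot_id"):
        ph = spot["ph_range"].iloc[0]
        by_strain = {s: g["abundance"].to_numpy(float) for s, g in spot.groupby("strain")}
        for a, b in pairs:
            xa, xb = by_strain.get(a, np.array([])), by_strain.get(b, np.array([]))
            if len(xa) < 2 or len(xb) < 2:
                skipped += 1
                continue
            ratio = signed_fold_change(float(xa.mean()), float(xb.mean()))
            if test == "paired":
                if len(xa) != len(xb):
                    raise DesignError("paired test requires equal replicate counts")
                p = float(stats.ttest_rel(xa, xb).pvalue)
            else:
                p = float(stats.ttest_ind(xa, xb, equal_var=(test == "student")).pvalue)
            rows.append(
                {
                    "spot_id": spot_id,
                    "pair": f"{a}-{b}",
                    "signed_ratio": ratio,
                    "p": p,
                    "n_a": len(xa),
                    "n_b": len(xb),
                    "ph_range": ph,
                    "altered": (abs(ratio) > ratio_threshold) and (p < p_threshold),
                }
            )
    if skipped:
        warnings.warn(f"{skipped} spot/pair contrasts skipped (<2 replicates in a group)")
    return pd.DataFrame(rows)


def dige_filter(contrasts: pd.DataFrame) -> pd.DataFrame:
    """Altered subset of a contrast table (strict 2.0-fold and p < 0.01 rule)."""
    return contrasts[contrasts["altered"]].reset_index(drop=True)


def count_by_range(altered: pd.DataFrame) -> pd.DataFrame:
    """Altered-spot counts per pI range and in total, one row per strain pair."""
    if altered.empty:
        return pd.DataFrame(columns=["pair", "acidic", "basic", "total"])
    if altered["ph_range"].isna().any() or (altered["ph_range"] == "").any():
        raise DesignError("altered spots without a pI-range tag")
    tags = altered["ph_range"].str.startswith("acidic").map({True: "acidic", False: "basic"})
    table = (
        altered.assign(range=tags)
        .groupby(["pair", "range"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["acidic", "basic"], fill_value=0)
    )
    table["total"] = table.sum(axis=1)
    return table.reset_index()
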