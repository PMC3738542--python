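"""2D-DIGE gel simulator with a Cy2 internal standard.

Every gel carries two samples (Cy3, Cy5) plus the pooled internal standard
(Cy2).  Ground truth is a per-spot, per-strain relative abundance versus the
pooled standard; spot volumes are lognormal around ``base_volume x
abundance`` so that the standardized abundance (sample / Cy2) recovers the
planted level in expectation.  Spots carry a pI-range tag (acidic 4-7 or
basic 6-11) matching the two IPG strip ranges of the assay; each range is
run as its own gel series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import DesignError

#: Column order of the DIGE TSV dialect.
DIGE_COLUMNS = [
    "spot_id",
    "gel_id",
    "ph_range",
    "cy2_vol",
    "cy3_vol",
    "cy5_vol",
    "sample_cy3",
    "sample_cy5",
]

ACIDIC, BASIC = "acidic_4_7", "basic_6_11"


@dataclass
class DigeTruth:
    """Ground truth of a simulated DIGE experiment.

    ``abundance`` is indexed by spot id with one column per strain: relative
    abundance versus the pooled internal standard (linear scale, > 0).
    ``ph_range`` tags each spot acidic or basic.
    """

    abundance: pd.DataFrame
    ph_range: pd.Series
    noise_sd_log2: float
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.abundance.to_numpy(float) <= 0):
            raise DesignError("planted abundances must be positive")
        if not self.ph_range.index.equals(self.abundance.index):
            raise DesignError("ph_range index must match abundance index")

    def planted_ratio(self, strain_a: str, strain_b: str) -> pd.Series:
        """Planted abundance ratio a/b per spot."""
        return self.abundance[strain_a] / self.abundance[strain_b]


def make_dige_truth(
    n_spots: int = 400,
    strains: tuple[str, ...] = ("HMS174", "RV308", "BL21"),
    n_b_vs_k: int | None = None,
    n_k_vs_k: int | None = None,
    effect_log2: float = 2.0,
    acidic_fraction: float = 0.85,
    noise_sd_log2: float = 0.1,
    seed: int = 0,
) -> DigeTruth:
    """Default truth: most spots flat, a planted minority altered.

    ``n_b_vs_k`` spots differ between the B strain and both K-12 strains and
    ``n_k_vs_k`` between the two K-12 strains, each by ``±effect_log2`` log2
    units (|ratio| 4 by default, above the 2.0-fold alteration threshold);
    the acidic range holds most spots, mirroring the acidic bias of the
    *E. coli* proteome.
    """
    if n_b_vs_k is None:
        n_b_vs_k = n_spots // 5  # 80 of the default 400 spots
    if n_k_vs_k is None:
        n_k_vs_k = max(1, n_spots // 33)  # 12 of the default 400
    if n_b_vs_k + n_k_vs_k > n_spots:
        raise DesignError("more planted spots than spots")
    rng = np.random.default_rng(seed)
    spots = [f"s{i:04d}" for i in range(n_spots)]
    log2_ab = pd.DataFrame(0.0, index=spots, columns=list(strains))
    picked = rng.choice(spots, size=n_b_vs_k + n_k_vs_k, replace=False)
    b_strain = strains[-1]
    for spot in picked[:n_b_vs_k]:
        log2_ab.loc[spot, b_strain] = effect_log2 * rng.choice([-1.0, 1.0])
    for spot in picked[n_b_vs_k:]:
        log2_ab.loc[spot, strains[0]] = effect_log2 * rng.choice([-1.0, 1.0])
    ph = pd.Series(
        np.where(rng.random(n_spots) < acidic_fraction, ACIDIC, BASIC), index=spots
    )
    return DigeTruth(
        abundance=np.exp2(log2_ab), ph_range=ph, noise_sd_log2=noise_sd_log2, seed=seed
    )


def gel_layout(samples: list[str], n_gels: int) -> list[tuple[str, str | None]]:
    """Assign samples pairwise to gels; the last slot may stay empty.

    Raises :class:`DesignError` when ``2 * n_gels`` slots cannot hold all
    samples.
    """
    if 2 * n_gels < len(samples):
        raise DesignError(
            f"{n_gels} gels provide {2 * n_gels} sample channels for {len(samples)} samples"
        )
    layout = []
    for i in range(n_gels):
        cy3 = samples[2 * i] if 2 * i < len(samples) else None
        cy5 = samples[2 * i + 1] if 2 * i + 1 < len(samples) else None
        if cy3 is None and cy5 is None:
            break
        layout.append((cy3, cy5))
    return layout


def simulate_dige(
    truth: DigeTruth,
    n_gels: int,
    samples: dict[str, str],
) -> list[pd.DataFrame]:
    """Simulate one gel series per pH range.

    ``samples`` maps sample id -> strain; every sample appears once per pH
    range, two per gel, with the Cy2 internal standard on every gel.  Returns
    one frame (:data:`DIGE_COLUMNS`) per gel across both ranges.
    """
    rng = np.random.default_rng(truth.seed + 2)
    unknown = set(samples.values()) - set(truth.abundance.columns)
    if unknown:
        raise DesignError(f"strains absent from truth: {sorted(unknown)}")
    sample_ids = list(samples)
    base_volume = pd.Series(
        rng.lognormal(mean=np.log(2.0e4), sigma=0.5, size=len(truth.abundance)),
        index=truth.abundance.index,
    )

    def volumes(spots: pd.Index, strain: str | None) -> np.ndarray:
        if strain is None:
            return np.full(len(spots), np.nan)
        level = truth.abundance.loc[spots, strain] if strain != "__std__" else 1.0
        noise = np.exp2(rng.normal(0.0, truth.noise_sd_log2, size=len(spots)))
        return base_volume.loc[spots].to_numpy() * np.asarray(level) * noise

    gels: list[pd.DataFrame] = []
    for ph_tag in (ACIDIC, BASIC):
        spots = truth.ph_range.index[truth.ph_range == ph_tag]
        if len(spots) == 0:
            continue
        for g, (cy3, cy5) in enumerate(gel_layout(sample_ids, n_gels)):
            gel_id = f"{ph_tag}_gel{g + 1}"
            frame = pd.DataFrame(
                {
                    "spot_id": spots,
                    "gel_id": gel_id,
                    "ph_range": ph_tag,
                    "cy2_vol": volumes(spots, "__std__"),
                    "cy3_vol": volumes(spots, samples.get(cy3) if cy3 else None),
                    "cy5_vol": volumes(spots, samples.get(cy5) if cy5 else None),
                    "sample_cy3": cy3 or "",
                    "sample_cy5": cy5 or "",
                }
            )
            gels.append(frame[DIGE_COLUMNS])
    return gels
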