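"""Two-channel microarray scan simulator (pooled-reference design).

Each hybridization carries one sample against the pooled reference, and every
sample is hybridized twice with the dye assignment exchanged (dye-swap pair).
Ground truth is a per-gene, per-strain log2 fold change *versus the pooled
reference*, plus a linear intensity-dependent dye bias per print-tip group:
the raw Cy5/Cy3 log ratio of a spot has expectation

    M_raw = orient * lfc(gene, strain) + a_tip + b_tip * A

where ``orient`` is +1 when the sample sits in the Cy5 channel and -1 in the
swapped member — i.e. the bias follows the dyes, not the sample, which is
exactly what dye-swap consolidation cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import DesignError

#: Column order of the GenePix-like scan TSV dialect.
SPOT_COLUMNS = [
    "block",
    "row",
    "column",
    "probe_id",
    "F_ch1",
    "F_ch2",
    "dye_ch1",
    "sample_ch1",
    "sample_ch2",
]

REFERENCE_SAMPLE = "reference_pool"


@dataclass(frozen=True)
class Hybridization:
    """One array: a sample vs the pooled reference with a dye orientation."""

    sample_id: str
    strain: str
    swapped: bool  # False: sample in Cy5 (ch1); True: sample in Cy3 (ch2)
    platform: str = "K12"


@dataclass
class ArrayTruth:
    """Ground truth of a simulated two-platform array experiment.

    ``lfc`` is indexed by gene with one column per strain (log2 vs the pooled
    reference).  ``base_log2`` is the per-gene reference-channel intensity in
    log2 units; ``dye_bias`` holds one (intercept, slope) row per print-tip
    group, applied as ``a + b * A`` in the dye orientation.
    """

    platform_genes: dict[str, list[str]]
    lfc: pd.DataFrame
    base_log2: pd.Series
    dye_bias: np.ndarray
    n_printtips: int
    spot_noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.lfc.to_numpy(float))):
            raise DesignError("planted lfc must be finite")
        all_platform = set().union(*map(set, self.platform_genes.values()))
        if not set(self.lfc.index) <= all_platform:
            raise DesignError("lfc contains genes absent from every platform")
        if self.dye_bias.shape != (self.n_printtips, 2):
            raise DesignError("dye_bias must have shape (n_printtips, 2)")

    @property
    def commonset(self) -> list[str]:
        sets = [set(g) for g in self.platform_genes.values()]
        common = set.intersection(*sets) if sets else set()
        return sorted(common)


# Planted Venn design: per-strain unique counts, pairwise-only counts and the
# triple overlap used to populate the default truth (union 347 of 3882).
DEFAULT_STRAINS = ("HMS174", "RV308", "BL21")
DEFAULT_VENN_DESIGN = {
    ("HMS174",): 50,
    ("RV308",): 29,
    ("BL21",): 155,
    ("HMS174", "RV308"): 13,
    ("HMS174", "BL21"): 14,
    ("RV308", "BL21"): 9,
    ("HMS174", "RV308", "BL21"): 77,
}


def make_array_truth(
    n_common: int = 3882,
    n_platform_only: tuple[int, int] = (300, 200),
    strains: tuple[str, ...] = DEFAULT_STRAINS,
    venn_design: dict[tuple[str, ...], int] | None = None,
    planted_lfc: float = 2.0,
    n_printtips: int = 16,
    spot_noise_sd: float = 0.3,
    dye_bias_scale: tuple[float, float] = (0.3, 0.04),
    seed: int = 0,
) -> ArrayTruth:
    """Build the default study-shaped truth.

    Two platforms (K12, B) share ``n_common`` genes; differentially expressed
    genes are planted inside the commonset according to ``venn_design`` with
    log2 fold change ``±planted_lfc`` (random sign per gene/strain).  Planted
    genes receive bright baselines (log2 intensity 9-13) so they are
    quantifiable; null genes span 7-13.
    """
    rng = np.random.default_rng(seed)
    common = [f"g{i:05d}" for i in range(n_common)]
    k12_only = [f"k12_{i:04d}" for i in range(n_platform_only[0])]
    b_only = [f"b_{i:04d}" for i in range(n_platform_only[1])]
    platform_genes = {"K12": common + k12_only, "B": common + b_only}
    all_genes = common + k12_only + b_only

    if venn_design is None:
        design = dict(DEFAULT_VENN_DESIGN)
        total = sum(design.values())
        if total > n_common // 2:
            # scale the study-shaped design down to small commonsets
            factor = (n_common // 2) / total
            design = {k: max(1, int(v * factor)) for k, v in design.items()}
    else:
        design = venn_design
    n_de = sum(design.values())
    if n_de > n_common:
        raise DesignError("Venn design larger than the commonset")
    de_pool = list(rng.choice(common, size=n_de, replace=False))
    lfc = pd.DataFrame(0.0, index=all_genes, columns=list(strains))
    pos = 0
    for combo, count in design.items():
        unknown = set(combo) - set(strains)
        if unknown:
            raise DesignError(f"unknown strains in Venn design: {sorted(unknown)}")
        for gene in de_pool[pos : pos + count]:
            for strain in combo:
                lfc.loc[gene, strain] = planted_lfc * rng.choice([-1.0, 1.0])
        pos += count

    base = pd.Series(rng.uniform(7.0, 13.0, size=len(all_genes)), index=all_genes)
    base.loc[de_pool] = rng.uniform(9.0, 13.0, size=n_de)
    bias = np.column_stack(
        [
            rng.uniform(-dye_bias_scale[0], dye_bias_scale[0], size=n_printtips),
            rng.uniform(-dye_bias_scale[1], dye_bias_scale[1], size=n_printtips),
        ]
    )
    return ArrayTruth(
        platform_genes=platform_genes,
        lfc=lfc,
        base_log2=base,
        dye_bias=bias,
        n_printtips=n_printtips,
        spot_noise_sd=spot_noise_sd,
        seed=seed,
    )


def reference_design(
    samples: dict[str, str], platform_of: dict[str, str] | None = None
) -> list[Hybridization]:
    """Dye-swap pair of hybridizations for every sample.

    ``samples`` maps sample id -> strain; ``platform_of`` maps strain ->
    platform (default: BL21 on the B array, everything else on K12).
    """
    hybs = []
    for sample_id, strain in samples.items():
        platform = (platform_of or {}).get(strain, "B" if strain == "BL21" else "K12")
        hybs.append(Hybridization(sample_id, strain, swapped=False, platform=platform))
        hybs.append(Hybridization(sample_id, strain, swapped=True, platform=platform))
    return hybs


def _spot_layout(n_spots: int, n_printtips: int) -> pd.DataFrame:
    """Assign spots to print-tip blocks in contiguous runs, grid coordinates within."""
    per_tip = int(np.ceil(n_spots / n_printtips))
    ncol = int(np.ceil(np.sqrt(per_tip)))
    block = np.arange(n_spots) // per_tip + 1
    within = np.arange(n_spots) % per_tip
    return pd.DataFrame(
        {"block": block, "row": within // ncol + 1, "column": within % ncol + 1}
    )


def simulate_microarray(
    truth: ArrayTruth, design: list[Hybridization]
) -> dict[str, pd.DataFrame]:
    """Simulate spot tables for every hybridization in ``design``.

    Returns a mapping array id -> GenePix-like frame (:data:`SPOT_COLUMNS`).
    Array ids encode sample and orientation, e.g. ``HMS174_r1_swap``.
    """
    rng = np.random.default_rng(truth.seed + 1)
    out: dict[str, pd.DataFrame] = {}
    for hyb in design:
        if hyb.platform not in truth.platform_genes:
            raise DesignError(f"unknown platform {hyb.platform!r}")
        if hyb.strain not in truth.lfc.columns:
            raise DesignError(f"sample {hyb.sample_id!r}: strain {hyb.strain!r} not in truth")
        genes = truth.platform_genes[hyb.platform]
        layout = _spot_layout(len(genes), truth.n_printtips)
        tip = layout["block"].to_numpy() - 1
        base = truth.base_log2.loc[genes].to_numpy(float)
        lfc = truth.lfc.loc[genes, hyb.strain].to_numpy(float)
        orient = -1.0 if hyb.swapped else 1.0
        a_bias = truth.dye_bias[tip, 0]
        b_bias = truth.dye_bias[tip, 1]
        noise = (
            rng.normal(0.0, truth.spot_noise_sd, size=len(genes))
            if truth.spot_noise_sd > 0
            else np.zeros(len(genes))
        )
        m_raw = orient * (lfc + noise) + a_bias + b_bias * base
        log_ch1 = base + 0.5 * m_raw  # Cy5
        log_ch2 = base - 0.5 * m_raw  # Cy3
        frame = layout.copy()
        frame["probe_id"] = genes
        frame["F_ch1"] = np.exp2(log_ch1)
        frame["F_ch2"] = np.exp2(log_ch2)
        frame["dye_ch1"] = "Cy5"
        frame["sample_ch1"] = REFERENCE_SAMPLE if hyb.swapped else hyb.sample_id
        frame["sample_ch2"] = hyb.sample_id if hyb.swapped else REFERENCE_SAMPLE
        name = f"{hyb.sample_id}_{'swap' if hyb.swapped else 'fwd'}"
        out[name] = frame[SPOT_COLUMNS]
    return out
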