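"""Reference-design two-color differential-expression analysis.

The stage mirrors the classic pooled-reference workflow: MA transform of
foreground intensities (no background correction), print-tip loess
normalization, dye-swap consolidation to one log ratio per gene per array,
an empirical-Bayes moderated one-sample t statistic across replicate arrays,
threshold filtering (A > 7.5, |M| > 1, p < 0.05 in at least one strain) and
Venn partitioning of the per-strain DE sets over the cross-platform
commonset.

The moderated t follows the standard hierarchical model for gene-wise
variances: sample variances s_g^2 with d_g degrees of freedom are shrunk
toward a common prior s_0^2 with d_0 prior degrees of freedom,

    s~_g^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g),
    t_g = mean_g / (s~_g / sqrt(n)),   df = d_0 + d_g,

where (d_0, s_0^2) are estimated by moment matching on log variances using
the exact moments of log chi-square distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, DomainError, InsufficientDataError

DEFAULT_SPAN = 0.4
DEFAULT_ITERATIONS = 3
MIN_SPOTS_PER_TIP = 10


# ---------------------------------------------------------------------------
# Spot-level transforms
# ---------------------------------------------------------------------------

def ma_transform(
    sample: np.ndarray | pd.Series, reference: np.ndarray | pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    """Per-spot (M, A) from foreground intensities.

    M = log2(sample / reference), A = 0.5 log2(sample * reference).  Spots
    with a non-positive intensity in either channel yield NaN in both
    statistics (flagged unusable, not floored).
    """
    s = np.asarray(sample, dtype=float)
    r = np.asarray(reference, dtype=float)
    usable = (s > 0) & (r > 0)
    m = np.full_like(s, np.nan)
    a = np.full_like(s, np.nan)
    m[usable] = np.log2(s[usable] / r[usable])
    a[usable] = 0.5 * np.log2(s[usable] * r[usable])
    return m, a


def spot_table_to_ma(spots: pd.DataFrame) -> pd.DataFrame:
    """MA statistics in sample-over-reference orientation for one scan.

    Expects the GenePix-like dialect (``F_ch1``/``F_ch2`` with
    ``sample_ch1``/``sample_ch2`` labels, channel 1 = Cy5).  Returns a frame
    with probe_id, block (print-tip group), M, A, sample and a ``swapped``
    flag (True when the sample sat in the Cy3 channel).
    """
    from .synthetic_data.arrays import REFERENCE_SAMPLE

    swapped = spots["sample_ch1"].eq(REFERENCE_SAMPLE)
    if swapped.nunique() > 1:
        raise DesignError("mixed dye orientation within one scan")
    is_swapped = bool(swapped.iloc[0])
    sample_int = spots["F_ch2"] if is_swapped else spots["F_ch1"]
    ref_int = spots["F_ch1"] if is_swapped else spots["F_ch2"]
    m, a = ma_transform(sample_int, ref_int)
    sample_id = spots["sample_ch2" if is_swapped else "sample_ch1"].iloc[0]
    return pd.DataFrame(
        {
            "probe_id": spots["probe_id"],
            "block": spots["block"],
            "M": m,
            "A": a,
            "sample": sample_id,
            "swapped": is_swapped,
        }
    )


def printtip_loess_normalize(
    ma: pd.DataFrame,
    span: float = DEFAULT_SPAN,
    iterations: int = DEFAULT_ITERATIONS,
    tip_column: str = "block",
) -> pd.DataFrame:
    """Subtract the loess trend of M on A within each print-tip group.

    Local-linear loess with tricube weights at fraction ``span`` and
    ``iterations`` robustifying passes.  Tip groups with fewer than
    ``MIN_SPOTS_PER_TIP`` usable spots fall back to median-centering with a
    warning.  Returns a copy with M replaced by the corrected values.
    """
    if not 0 < span <= 1:
        raise DomainError("span must lie in (0, 1]")
    out = ma.copy()
    corrected = out["M"].to_numpy(float).copy()
    for tip, idx in out.groupby(tip_column).groups.items():
        m = out.loc[idx, "M"].to_numpy(float)
        a = out.loc[idx, "A"].to_numpy(float)
        usable = np.isfinite(m) & np.isfinite(a)
        pos = np.flatnonzero(out.index.isin(idx))
        if usable.sum() < MIN_SPOTS_PER_TIP:
            warnings.warn(
                f"print-tip group {tip!r}: {usable.sum()} usable spots; median-centering",
                stacklevel=2,
            )
            fit = np.nanmedian(m) if usable.any() else 0.0
            corrected[pos] = m - fit
            continue
        trend = lowess(
            m[usable], a[usable], frac=span, it=iterations, return_sorted=False
        )
        res = m.copy()
        res[usable] = m[usable] - trend
        corrected[pos] = res
    out["M"] = corrected
    return out


def consolidate_dye_swap(arrays: list[pd.DataFrame], probe_map: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene M and A for one sample from its dye-swap pair of arrays.

    The swapped member's M is stored sample-over-reference already (see
    :func:`spot_table_to_ma`), so consolidation is: average replicate spots
    per probe within each array, map probes to genes (``probe_map``:
    probe -> gene; identity when omitted), then average M and A across the
    pair.  Genes present on only one member use that member and are flagged.
    """
    if not arrays:
        raise InsufficientDataError("no arrays to consolidate")
    per_array = []
    for i, arr in enumerate(arrays):
        grouped = (
            arr.dropna(subset=["M", "A"])
            .groupby("probe_id")[["M", "A"]]
            .mean()
            .reset_index()
        )
        if probe_map is not None:
            grouped["gene"] = grouped["probe_id"].map(probe_map)
            grouped = grouped.dropna(subset=["gene"]).groupby("gene")[["M", "A"]].mean()
        else:
            grouped = grouped.set_index("probe_id")[["M", "A"]]
        grouped["array"] = i
        per_array.append(grouped)
    stacked = pd.concat(per_array)
    agg = stacked.groupby(level=0).agg(
        M=("M", "mean"), A=("A", "mean"), n_arrays=("array", "nunique")
    )
    agg["partial"] = agg["n_arrays"] < len(arrays)
    agg.index.name = "gene"
    return agg


# ---------------------------------------------------------------------------
# Moderated statistics
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise DomainError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Prior degrees of freedom d0 and scale s0^2 from gene-wise variances.

    Moment matching on z = log(s^2): under the hierarchical model z is a
    shifted log-F variate with E[z] and Var[z] expressible via digamma /
    trigamma functions of (df/2, d0/2).  An excess of Var[z] over
    trigamma(df/2) identifies a finite d0; otherwise d0 is infinite and the
    variances are fully shrunk to s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise InsufficientDataError("need >= 2 positive variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


@dataclass
class ModeratedTResult:
    """Moderated one-sample t statistics for a gene x array matrix."""

    table: pd.DataFrame  # columns: mean, s2, s2_post, t, p, t_ordinary, p_ordinary
    d0: float
    s0_sq: float
    df_residual: int

    @property
    def df_total(self) -> float:
        return self.d0 + self.df_residual


def moderated_t(m_matrix: pd.DataFrame, prior_df: float | None = None) -> ModeratedTResult:
    """Empirical-Bayes moderated one-sample t for per-gene log ratios.

    ``m_matrix`` holds one row per gene and one column per replicate array.
    ``prior_df`` overrides the estimated d0 (0 recovers the ordinary t;
    ``numpy.inf`` shrinks every variance to s0^2).  Two-sided p-values use a
    Student t with d0 + (n - 1) degrees of freedom.  Ordinary-t columns are
    emitted alongside for comparison.
    """
    x = m_matrix.to_numpy(float)
    n = x.shape[1]
    if n < 2:
        raise InsufficientDataError("need >= 2 replicate arrays")
    mean = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    dg = n - 1
    d0, s0_sq = estimate_variance_prior(s2, dg)
    if prior_df is not None:
        d0 = float(prior_df)
        if not np.isfinite(d0) and prior_df != 0:
            d0 = np.inf
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = dg
    else:
        s2_post = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = mean / np.sqrt(s2_post / n)
        t_ord = mean / np.sqrt(s2 / n)
    if np.isinf(df_total):
        p_mod = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_mod = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_ord = 2.0 * stats.t.sf(np.abs(t_ord), dg)
    table = pd.DataFrame(
        {
            "mean": mean,
            "s2": s2,
            "s2_post": s2_post,
            "t": t_mod,
            "p": p_mod,
            "t_ordinary": t_ord,
            "p_ordinary": p_ord,
        },
        index=m_matrix.index,
    )
    return ModeratedTResult(table=table, d0=d0, s0_sq=s0_sq, df_residual=dg)


# ---------------------------------------------------------------------------
# Filtering and set partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DEThresholds:
    """Candidate-gene thresholds: A > a_min, |M| > m_min, p < p_max (strict)."""

    a_min: float = 7.5
    m_min: float = 1.0
    p_max: float = 0.05


def filter_de(
    results: pd.DataFrame, thresholds: DEThresholds = DEThresholds()
) -> pd.DataFrame:
    """Per-strain DE flags and the union flag.

    ``results`` is a long frame with columns gene, strain, M, A, p.  A gene
    is DE in a strain iff A > a_min, |M| > m_min and p < p_max all hold
    (strict inequalities); it enters the union iff DE in at least one
    strain.  Genes with missing A or p are excluded with a warning.  Returns
    a wide boolean frame indexed by gene, one column per strain plus
    ``in_union``; BH-adjusted p-values are reported informationally in
    long-format outputs, not used by the filter.
    """
    req = {"gene", "strain", "M", "A", "p"}
    if not req <= set(results.columns):
        raise DesignError(f"results must have columns {sorted(req)}")
    bad = results[["M", "A", "p"]].isna().any(axis=1)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} gene/strain records with missing M, A or p excluded")
        results = results[~bad]
    flags = (
        results.assign(
            de=(results["A"] > thresholds.a_min)
            & (results["M"].abs() > thresholds.m_min)
            & (results["p"] < thresholds.p_max)
        )
        .pivot_table(index="gene", columns="strain", values="de", fill_value=False, aggfunc="any")
        .astype(bool)
    )
    flags["in_union"] = flags.any(axis=1)
    return flags


def adjust_p(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values (informational)."""
    adj = np.full(len(p), np.nan)
    ok = p.notna().to_numpy()
    if ok.any():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.Series(adj, index=p.index, name="p_adj")


@dataclass
class VennPartition:
    """Disjoint region counts of up to three DE sets over a universe."""

    strains: tuple[str, ...]
    region_counts: dict[tuple[str, ...], int]
    complement: int
    universe_size: int

    @property
    def union(self) -> int:
        return self.universe_size - self.complement

    def count(self, *strains: str) -> int:
        """Count of the disjoint region DE in exactly the given strains."""
        return self.region_counts[tuple(sorted(strains))]

    def to_dict(self) -> dict[str, int]:
        out = {"|".join(k): v for k, v in self.region_counts.items()}
        out["none"] = self.complement
        out["universe"] = self.universe_size
        out["union"] = self.union
        return out


def venn_partition(flags: pd.DataFrame, universe: list[str]) -> VennPartition:
    """Partition the universe by per-strain DE membership.

    ``flags`` is a boolean frame indexed by gene (strain columns only; an
    ``in_union`` column is ignored).  Genes flagged outside the universe
    raise; universe genes without flags count as not DE.
    """
    strains = tuple(c for c in flags.columns if c != "in_union")
    uni = pd.Index(universe)
    if uni.has_duplicates:
        raise DesignError("universe contains duplicate genes")
    outside = flags.index.difference(uni)
    if len(outside):
        raise DesignError(f"flags for {len(outside)} genes outside the universe")
    full = flags.reindex(uni, fill_value=False)[list(strains)].astype(bool)
    counts: dict[tuple[str, ...], int] = {}
    complement = 0
    membership = full.to_numpy()
    for pattern, count in zip(*np.unique(membership, axis=0, return_counts=True)):
        combo = tuple(sorted(s for s, m in zip(strains, pattern) if m))
        if combo:
            counts[combo] = int(count)
        else:
            complement = int(count)
    # ensure all 2^k - 1 regions appear, zero-filled
    from itertools import combinations

    for r in range(1, len(strains) + 1):
        for combo in combinations(sorted(strains), r):
            counts.setdefault(combo, 0)
    return VennPartition(
        strains=strains,
        region_counts=counts,
        complement=complement,
        universe_size=len(uni),
    )


def intersect_platforms(genes_a: list[str], genes_b: list[str]) -> list[str]:
    """Sorted case-normalized intersection of two platform gene lists."""
    if not genes_a or not genes_b:
        raise DesignError("platform gene lists must be non-empty")
    a = {g.lower() for g in genes_a}
    b = {g.lower() for g in genes_b}
    return sorted(a & b)


# ---------------------------------------------------------------------------
# End-to-end per-strain analysis
# ---------------------------------------------------------------------------

def analyze_scans(
    scans: dict[str, pd.DataFrame],
    sample_strain: dict[str, str],
    probe_map: pd.Series | None = None,
    span: float = DEFAULT_SPAN,
    iterations: int = DEFAULT_ITERATIONS,
    thresholds: DEThresholds = DEThresholds(),
    universe: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, VennPartition]:
    """Scan tables -> per-gene results, DE flags and Venn partition.

    Each scan is MA-transformed and print-tip loess normalized; per strain,
    every orientation-corrected array is one replicate column for the
    moderated t.  ``universe`` defaults to genes measured in every strain.
    Returns (long results frame, flags, venn).
    """
    per_strain_arrays: dict[str, list[pd.Series]] = {}
    per_strain_a: dict[str, list[pd.Series]] = {}
    for name, spots in scans.items():
        ma = spot_table_to_ma(spots)
        norm = printtip_loess_normalize(ma, span=span, iterations=iterations)
        sample = norm["sample"].iloc[0]
        strain = sample_strain.get(sample)
        if strain is None:
            raise DesignError(f"scan {name!r}: sample {sample!r} not in design")
        cons = consolidate_dye_swap([norm], probe_map=probe_map)
        per_strain_arrays.setdefault(strain, []).append(cons["M"])
        per_strain_a.setdefault(strain, []).append(cons["A"])

    rows = []
    for strain, columns in per_strain_arrays.items():
        m_matrix = pd.concat(columns, axis=1)
        m_matrix.columns = range(m_matrix.shape[1])
        mod = moderated_t(m_matrix.dropna())
        a_mean = pd.concat(per_strain_a[strain], axis=1).mean(axis=1)
        tab = mod.table
        frame = pd.DataFrame(
            {
                "gene": tab.index,
                "strain": strain,
                "M": tab["mean"].to_numpy(),
                "A": a_mean.reindex(tab.index).to_numpy(),
                "t": tab["t"].to_numpy(),
                "p": tab["p"].to_numpy(),
                "p_ordinary": tab["p_ordinary"].to_numpy(),
                "n_arrays": m_matrix.shape[1],
            }
        )
        frame["p_adj"] = adjust_p(frame["p"]).to_numpy()
        rows.append(frame)
    results = pd.concat(rows, ignore_index=True)
    flags = filter_de(results, thresholds=thresholds)
    if universe is None:
        measured = results.pivot_table(index="gene", columns="strain", values="M", aggfunc="size")
        universe = sorted(measured.dropna().index)
    flags = flags.loc[flags.index.intersection(universe)]
    venn = venn_partition(flags.drop(columns="in_union"), universe)
    results["de"] = results.set_index(["gene", "strain"]).index.map(
        lambda gs: bool(
            flags.at[gs[0], gs[1]] if gs[0] in flags.index and gs[1] in flags.columns else False
        )
    )
    return results, flags, venn
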