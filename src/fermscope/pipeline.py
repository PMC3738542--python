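"""End-to-end orchestration: simulate -> process -> arrays -> gels -> integrate.

Every stage is deterministic given the configured seed, writes its artifacts
under the output directory and records them in a manifest with SHA-256
hashes, so a run is regenerable from config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import process_metrics as pm
from . import proteome, transcriptome
from .elements import BIOMASS, GLUCOSE, carbon_fraction
from .errors import FermscopeError
from .integration import integrate_contrasts
from .annotation import category_tally
from .synthetic_data import (
    make_array_truth,
    make_dige_truth,
    reference_design,
    scenario_for_preset,
    simulate_batch,
    simulate_dige,
    simulate_microarray,
)

STRAIN_PRESET_OF = {
    "HMS174": "K12_HMS_like",
    "RV308": "K12_RV_like",
    "BL21": "B_like",
}


@dataclass
class PipelineConfig:
    """Tunable knobs of a full synthetic-study run."""

    seed: int = 0
    strains: tuple[str, ...] = ("HMS174", "RV308", "BL21")
    n_replicates: int = 3
    noise_cv: float = 0.02
    # transcriptome
    n_common_genes: int = 3882
    loess_span: float = transcriptome.DEFAULT_SPAN
    loess_iterations: int = transcriptome.DEFAULT_ITERATIONS
    a_min: float = 7.5
    m_min: float = 1.0
    p_max: float = 0.05
    # proteome
    n_spots: int = 400
    dige_ratio_threshold: float = 2.0
    dige_p_threshold: float = 0.01
    n_gels_per_range: int = 5
    # reporting
    round_decimals: int = 2

    def validate(self) -> None:
        if min(self.a_min, self.m_min, self.p_max, self.dige_ratio_threshold, self.dige_p_threshold) <= 0:
            raise FermscopeError("thresholds must be positive")
        if self.n_replicates < 2:
            raise FermscopeError("need >= 2 replicate cultivations")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FermscopeError(f"unknown config keys: {sorted(unknown)}")
        if "strains" in raw:
            raw["strains"] = tuple(raw["strains"])
        return cls(**raw)


def _log(msg: str, t0: float) -> None:
    print(f"[fermscope +{time.perf_counter() - t0:6.1f}s] {msg}", file=sys.stderr)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_process_stage(config: PipelineConfig, out: Path) -> dict:
    """Simulate replicate cultivations per strain and compute process metrics."""
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    recoveries = {}
    for si, strain in enumerate(config.strains):
        preset = STRAIN_PRESET_OF[strain]
        for rep in range(config.n_replicates):
            seed = config.seed * 1009 + si * 101 + rep
            scenario = scenario_for_preset(preset, noise_cv=config.noise_cv, seed=seed % (2**31))
            result = simulate_batch(scenario)
            path = out / f"{strain}_r{rep + 1}.tsv"
            result.measured.to_tsv(path)
            k = scenario.kinetics
            t = result.truth.time
            window = (k.lag_duration + 0.5, float(t[-1]) - 0.5)
            fit = pm.fit_growth_rate(result.measured, window=window)
            end = result.measured.data.iloc[-1]
            rows.append(
                {
                    "strain": strain,
                    "replicate": rep + 1,
                    "mu_fit": fit.rate,
                    "mu_average": pm.average_growth_rate(result.measured),
                    "end_cdm": float(end["cdm_g_per_L"]),
                    "max_acetate": float(result.measured.data["acetate_g_per_L"].max()),
                    "series": path.name,
                }
            )
            if rep == 0:
                # carbon recovery on the noiseless trajectory of one replicate
                consumed = scenario.S0 - float(result.truth.data["glucose_g_per_L"].iloc[-1])
                total_c = (
                    consumed * carbon_fraction(GLUCOSE)
                    + scenario.X0 * carbon_fraction(BIOMASS)
                ) * scenario.volume
                balance = pm.carbon_balance(result.truth, total_input_carbon=total_c)
                recoveries[strain] = balance.recovery
    runs = pd.DataFrame(rows)
    summary_rows = []
    for strain, grp in runs.groupby("strain", sort=False):
        for metric in ("mu_fit", "end_cdm", "max_acetate"):
            s = pm.summarize_replicates(grp[metric])
            summary_rows.append(
                {"strain": strain, "metric": metric, "mean": s.mean, "sem": s.sem, "n": s.n}
            )
        yld = pm.yield_coefficients(
            final_cdm=float(grp["end_cdm"].mean()),
            substrate0=scenario.S0,
            byproduct_acetate=float(grp["max_acetate"].mean()),
        )
        summary_rows.append(
            {"strain": strain, "metric": "yxs_corrected", "mean": yld.yxs_corrected, "sem": 0.0, "n": s.n}
        )
    summary = pd.DataFrame(summary_rows)
    runs.to_csv(out / "runs.tsv", sep="\t", index=False)
    summary.round(config.round_decimals).to_csv(out / "summary.tsv", sep="\t", index=False)
    (out / "carbon_recovery.json").write_text(json.dumps(recoveries, indent=2))
    return {"runs": runs, "summary": summary, "carbon_recovery": recoveries}


def transcriptome_stage(config: PipelineConfig, out: Path) -> dict:
    """Simulate the pooled-reference array experiment and run the DE analysis."""
    out.mkdir(parents=True, exist_ok=True)
    truth = make_array_truth(
        n_common=config.n_common_genes, strains=config.strains, seed=config.seed
    )
    samples = {
        f"{strain}_r{rep + 1}": strain
        for strain in config.strains
        for rep in range(config.n_replicates)
    }
    design = reference_design(samples)
    scans = simulate_microarray(truth, design)
    thresholds = transcriptome.DEThresholds(
        a_min=config.a_min, m_min=config.m_min, p_max=config.p_max
    )
    universe = transcriptome.intersect_platforms(
        truth.platform_genes["K12"], truth.platform_genes["B"]
    )
    results, flags, venn = transcriptome.analyze_scans(
        scans,
        sample_strain=samples,
        span=config.loess_span,
        iterations=config.loess_iterations,
        thresholds=thresholds,
        universe=universe,
    )
    results.round(4).to_csv(out / "expression.tsv", sep="\t", index=False)
    (out / "venn.json").write_text(json.dumps(venn.to_dict(), indent=2))
    return {"truth": truth, "results": results, "flags": flags, "venn": venn}


def proteome_stage(config: PipelineConfig, out: Path) -> dict:
    """Simulate the DIGE gel series and run the ratio analysis."""
    out.mkdir(parents=True, exist_ok=True)
    truth = make_dige_truth(
        n_spots=config.n_spots, strains=config.strains, seed=config.seed
    )
    samples = {
        f"{strain}_r{rep + 1}": strain
        for strain in config.strains
        for rep in range(config.n_replicates)
    }
    gels = simulate_dige(truth, n_gels=config.n_gels_per_range, samples=samples)
    for gel in gels:
        gel.to_csv(out / f"{gel['gel_id'].iloc[0]}.tsv", sep="\t", index=False)
    abundances = proteome.standardize_abundance(gels)
    pairs = [(b, a) for a, b in [("HMS174", "BL21"), ("RV308", "BL21"), ("RV308", "HMS174")]]
    pairs = [p for p in pairs if set(p) <= set(config.strains)]
    contrasts = proteome.dige_contrasts(
        abundances,
        sample_strain=samples,
        pairs=pairs or None,
        ratio_threshold=config.dige_ratio_threshold,
        p_threshold=config.dige_p_threshold,
    )
    altered = proteome.dige_filter(contrasts)
    counts = proteome.count_by_range(altered)
    contrasts.round(4).to_csv(out / "contrasts.tsv", sep="\t", index=False)
    counts.to_csv(out / "altered_counts.tsv", sep="\t", index=False)
    return {"truth": truth, "contrasts": contrasts, "altered": altered, "counts": counts}


def integration_stage(
    config: PipelineConfig,
    array_truth,
    dige_truth,
    results: pd.DataFrame,
    contrasts: pd.DataFrame,
    out: Path,
) -> dict:
    """Join protein and transcript contrasts through a synthetic spot->gene map."""
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 3)
    spots = list(dige_truth.abundance.index)
    commonset = array_truth.commonset
    genes = list(rng.choice(commonset, size=len(spots), replace=False))
    spot_gene = pd.DataFrame({"spot_id": spots, "gene": genes})
    gene_m = results.pivot_table(index="gene", columns="strain", values="M")
    table = integrate_contrasts(gene_m, contrasts, spot_gene).table
    table.round(4).to_csv(out / "integrated.tsv", sep="\t", index=False)
    spot_gene.to_csv(out / "spot_gene_map.tsv", sep="\t", index=False)
    return {"table": table, "spot_gene_map": spot_gene}


def annotation_stage(config: PipelineConfig, flags: pd.DataFrame, out: Path) -> dict:
    """Tally DE genes into a synthetic functional-category map."""
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 4)
    vocabulary = [
        "transport",
        "motility",
        "iron_acquisition",
        "transcription_regulation",
        "carbohydrate_metabolism",
        "membrane",
        "amino_acid_biosynthesis",
    ]
    genes = list(flags.index)
    n_terms = rng.integers(0, 3, size=len(genes))
    records = [
        (g, t)
        for g, k in zip(genes, n_terms)
        for t in rng.choice(vocabulary, size=k, replace=False)
    ]
    annotation = pd.DataFrame(records, columns=["gene", "term"])
    union_genes = flags.index[flags["in_union"]]
    tally = category_tally(union_genes, annotation, k=10)
    tally.to_csv(out / "category_tally.tsv", sep="\t", index=False)
    annotation.to_csv(out / "annotation_map.tsv", sep="\t", index=False)
    return {"tally": tally, "annotation": annotation}


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage in dependency order; returns the in-memory results."""
    t0 = time.perf_counter()
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _log("process stage", t0)
    process = simulate_process_stage(config, out / "process")
    _log("transcriptome stage", t0)
    trans = transcriptome_stage(config, out / "transcriptome")
    _log("proteome stage", t0)
    prot = proteome_stage(config, out / "proteome")
    _log("integration stage", t0)
    integ = integration_stage(
        config, trans["truth"], prot["truth"], trans["results"], prot["contrasts"],
        out / "integration",
    )
    _log("annotation stage", t0)
    annot = annotation_stage(config, trans["flags"], out / "annotation")
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*.tsv")) + sorted(out.rglob("*.json"))
            if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    _log("done", t0)
    return {
        "process": process,
        "transcriptome": trans,
        "proteome": prot,
        "integration": integ,
        "annotation": annot,
        "manifest": manifest,
    }
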