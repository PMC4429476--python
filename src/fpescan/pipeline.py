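"""End-to-end reproducible runs: simulate, clean, test, report.

``run_pipeline`` wires the synthetic-cohort generator, the null-panel
simulator with an optionally embedded protective locus, PLINK text and BED
round trips, QC, tiered association and top-hit reporting into one seeded
run that writes every intermediate file plus a manifest (inputs, seeds,
per-stage counts, SHA-256 checksums of all outputs).  Two runs with the
same configuration produce byte-identical outputs.

``reproduce_figures`` emits the plotted quantities of the three figure
families as TSV tables (score distributions, power curves, family
simulations) so the figures can be regenerated by any plotting tool.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, genotypes, liability, model, power

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "reproduce_figures"]

log = logging.getLogger("fpescan")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, message: str, manifest: dict):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage
        self.manifest = manifest


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one pipeline run."""

    scenario: str = "embedded"  # "embedded" or "null"
    preset: str = "calibrated_4to1"
    n_affected: int = 208
    n_unaffected: int = 151
    n_tier1: int = 451
    n_chrx_other: int = 6_504
    n_autosomal: int = 2_000
    missing_rate: float = 0.0
    tier: int = 1
    assoc_model: str = "dominant"
    test_method: str = "fisher"
    top_k: int = 5
    seed: int = 0
    out_dir: str = "fpescan_run"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _embedded_locus_spec(preset_name: str, seed: int) -> genotypes.EmbeddedLocusSpec:
    """Carrier-frequency targets implied by a model preset.

    Affected females carry protection at the model's predicted rate;
    unaffected females at the population-limit carrier rate (the control
    bound of the predicted contrast).
    """
    params = model.get_preset(preset_name)
    locus = model.predict_case_control_freqs(params)
    case_carrier = 1.0 - locus.case_allele1_freq / 100.0
    control_carrier = 1.0 - locus.control_allele1_freq_bound / 100.0
    return genotypes.EmbeddedLocusSpec(
        target_case_carrier_freq=case_carrier,
        target_control_carrier_freq=control_carrier,
        allele2_freq=params.protective_allele_freq,
        seed=seed + 7,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> write -> QC -> tiered association -> report.

    Returns the manifest dict (also written to ``manifest.json`` in the
    output directory).  Any stage error aborts with a
    :class:`PipelineError` carrying the partial manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "stages": {},
        "files": {},
    }
    stage = "simulate-cohort"
    try:
        if config.n_affected + config.n_unaffected == 0:
            raise ValueError("empty cohort")
        cohort = genotypes.simulate_cohort(
            config.n_affected, config.n_unaffected, seed=config.seed
        )
        manifest["stages"][stage] = {
            "seed": config.seed,
            "n_individuals": len(cohort),
            "n_affected": int(cohort.affected.sum()),
        }
        log.info("%s: %d individuals", stage, len(cohort))

        stage = "simulate-genotypes"
        panel = genotypes.SnpPanelSpec(
            n_tier1=config.n_tier1,
            n_chrx_other=config.n_chrx_other,
            n_autosomal=config.n_autosomal,
            missing_rate=config.missing_rate,
            seed=config.seed + 1,
        )
        geno = genotypes.simulate_null_genotypes(panel, cohort)
        if config.scenario == "embedded":
            geno = genotypes.embed_fpe_locus(
                geno, cohort, _embedded_locus_spec(config.preset, config.seed)
            )
        elif config.scenario != "null":
            raise ValueError(f"unknown scenario {config.scenario!r}")
        manifest["stages"][stage] = {
            "seed": config.seed + 1,
            "n_snps": geno.n_snps,
            "scenario": config.scenario,
        }

        stage = "write-inputs"
        cohort.to_tsv(out / "cohort.tsv")
        genotypes.write_plink_text(geno, cohort, out / "genotypes")
        genotypes.write_bed(genotypes.DEFAULT_ESCAPE_REGIONS, out / "escape.bed")
        genotypes.write_bed(genotypes.DEFAULT_Y_HOMOLOGY_REGIONS, out / "yhom.bed")
        manifest["stages"][stage] = {"n_files": 5}

        stage = "qc"
        clean, report = assoc.apply_qc(geno, affected=cohort.affected)
        manifest["stages"][stage] = {
            "samples_removed_call_rate": report.samples_removed_call_rate,
            "snps_removed_missingness": report.snps_removed_missingness,
            "snps_removed_maf": report.snps_removed_maf,
            "snps_removed_hwe": report.snps_removed_hwe,
            "n_snps_out": report.n_snps_out,
        }
        if clean.n_snps == 0:
            raise ValueError("no SNPs left after QC")

        stage = "association"
        tier_spec = assoc.TierSpec(
            tier=config.tier,
            escape_regions=genotypes.DEFAULT_ESCAPE_REGIONS,
            y_homology_regions=genotypes.DEFAULT_Y_HOMOLOGY_REGIONS,
        )
        results = assoc.run_association(
            clean, cohort, tier_spec, model=config.assoc_model,
            method=config.test_method,
        )
        if results.empty:
            raise ValueError("association produced no testable SNPs")
        results_path = out / "results.tsv"
        results.to_csv(results_path, sep="\t", index=False, float_format="%.6g")
        top = assoc.top_k_report(results, k=config.top_k)
        top_path = out / "top_hits.tsv"
        top.to_csv(top_path, sep="\t", index=False, float_format="%.6g")
        n_sig = int((results["p_corrected"] <= 0.05).sum())
        manifest["stages"][stage] = {
            "n_tests": int(results.attrs["n_tests"]),
            "n_significant_corrected": n_sig,
            "top_hit": top.iloc[0]["snp"],
            "top_hit_p": float(top.iloc[0]["p"]),
            "top_hit_p_corrected": float(top.iloc[0]["p_corrected"]),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc), manifest) from exc

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def reproduce_figures(which: str, out_dir, seed: int = 0) -> dict:
    """Emit figure data tables as TSV; returns {table name: path}.

    ``fig1``: observed-style and expected threshold-model score
    distributions plus the four factor scenarios (many/few/one/no
    protective factors).  ``fig2``: power-versus-size curves for
    female-only and 5.25:1 mixed designs under the half-attribution model.
    ``s12``: multiplex-ascertainment liabilities for the 0.66-SD and
    0.17-SD sex offsets with per-sex dip statistics.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = seed
    paths: dict = {}

    if which == "fig1":
        rng = np.random.default_rng(rng_seed)
        # threshold-model expectation at the observed male/female cohort shapes
        for label, (n, n_aff, mean, sd) in {
            "male": (927, 832, 90.0, 30.0),
            "female": (394, 243, 60.0, 45.0),
        }.items():
            observed = rng.normal(mean, sd, size=n)
            sim, thr = liability.expected_threshold_distribution(
                observed, n_aff, seed=rng_seed + 1
            )
            t = pd.DataFrame({"score": np.sort(sim)})
            t["affected"] = t["score"] >= thr
            p = out / f"fig1_expected_{label}.tsv"
            t.to_csv(p, sep="\t", index=False, float_format="%.4f")
            paths[f"expected_{label}"] = p
        scenarios = {
            "E_many_factors": liability.FactorScenario(k=20, factor_effect=4.5, seed=rng_seed),
            "F_few_factors": liability.FactorScenario(k=3, factor_effect=30.0, seed=rng_seed),
            "G_single_factor": liability.FactorScenario(k=1, factor_effect=90.0, seed=rng_seed),
            "H_no_factor": liability.FactorScenario(k=0, seed=rng_seed),
        }
        for label, spec in scenarios.items():
            t = liability.simulate_factor_scenarios(spec)
            p = out / f"fig1_{label}.tsv"
            t.to_csv(p, sep="\t", index=False, float_format="%.4f")
            paths[label] = p
    elif which == "fig2":
        params = model.get_preset("half_fpe_5.25to1")
        sizes = [250, 500, 1000, 2000, 2678, 4000, 8000]
        curve = power.power_curve(params, sizes, max_enum=0)  # normal approx
        p = out / "fig2_power_curve.tsv"
        curve.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths["power_curve"] = p
    elif which == "s12":
        rows = []
        for offset in (0.66, 0.17):
            cfg = liability.FamilySimConfig(
                n_families=50_000,
                sex_liability_offset=offset,
                diagnostic_threshold=liability.tune_threshold(0.66, 4.0),
                seed=rng_seed,
            )
            fam = liability.simulate_multiplex_ascertainment(cfg)
            p = out / f"s12_children_offset{offset}.tsv"
            fam.to_csv(p, sep="\t", index=False, float_format="%.4f")
            paths[f"children_{offset}"] = p
            for sex in ("male", "female"):
                scores = fam.loc[fam["sex"] == sex, "liability"].to_numpy()
                from .dip import dip_statistic

                rows.append(
                    {
                        "offset_sd": offset,
                        "sex": sex,
                        "n_children": len(scores),
                        "dip": dip_statistic(scores),
                        "realized_sex_bias": fam.attrs["realized_sex_bias"],
                    }
                )
        t = pd.DataFrame(rows)
        p = out / "s12_dip_summary.tsv"
        t.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths["dip_summary"] = p
    else:
        raise ValueError(f"unknown figure set {which!r}")
    return paths
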