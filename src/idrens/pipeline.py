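"""End-to-end orchestration: ensembles -> descriptors -> comparisons plus
the synthetic assay stages, with a manifest recording config hash, seeds,
per-stage timing and the produced file set."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from idrens import assay, compare, descriptors, sequences, trajio
from idrens.config import PipelineConfig
from idrens.sampler import Ensemble, InteractionFlags, sample_ensemble

logger = logging.getLogger("idrens")

EV_LABEL = "EV"  # excluded-volume reference, sampled on the WT sequence


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage.  Outputs of completed
    stages are retained on disk."""


def variant_seed(base_seed: int, label: str) -> int:
    """Deterministic per-variant seed derived from the run's base seed."""
    idx = (sequences.VARIANT_NAMES + (EV_LABEL,)).index(label)
    return int(np.random.SeedSequence([base_seed, idx]).generate_state(1)[0])


def simulate_stage(config: PipelineConfig, outdir: Path) -> dict[str, Ensemble]:
    """Sample every configured variant plus the excluded-volume reference and
    write PDB/XYZ trajectories with provenance sidecars."""
    traj_dir = outdir / "trajectories"
    traj_dir.mkdir(parents=True, exist_ok=True)
    ensembles: dict[str, Ensemble] = {}
    for name in config.variants:
        seq = sequences.get_variant(name)
        params = config.sampler_params(variant_seed(config.base_seed, name))
        t0 = time.perf_counter()
        ens = sample_ensemble(seq, params)
        logger.info("sampled %s: %d conformations, acceptance %.3f, %.1fs",
                    name, len(ens), ens.acceptance_rate, time.perf_counter() - t0)
        trajio.write_trajectory(ens, traj_dir / f"{name}.pdb")
        trajio.write_trajectory(ens, traj_dir / f"{name}.xyz")
        ensembles[name] = ens
    # EV reference on the WT sequence, sterics only
    seq = sequences.get_variant("WT")
    params = config.sampler_params(
        variant_seed(config.base_seed, EV_LABEL),
        interactions=InteractionFlags(sterics=True, electrostatics=False,
                                      helix_bias=False),
    )
    ens = sample_ensemble(seq, params)
    trajio.write_trajectory(ens, traj_dir / f"{EV_LABEL}.pdb")
    trajio.write_trajectory(ens, traj_dir / f"{EV_LABEL}.xyz")
    ensembles[EV_LABEL] = ens
    return ensembles


def descriptor_stage(config: PipelineConfig, ensembles: dict[str, Ensemble],
                     outdir: Path) -> dict[str, descriptors.DescriptorTable]:
    desc_dir = outdir / "descriptors"
    tables = {}
    ev = ensembles[EV_LABEL]
    for name, ens in ensembles.items():
        table = descriptors.compute_descriptors(ens, name=name)
        table.write(desc_dir)
        tables[name] = table
        if name != EV_LABEL:
            smap = descriptors.scaling_map(ens, ev)
            residues = np.arange(ens.sequence.start_number,
                                 ens.sequence.start_number + ens.n_res)
            pd.DataFrame(smap.ratio, index=residues, columns=residues).to_csv(
                desc_dir / f"{name}_scaling_map.csv")
    return tables


def compare_stage(config: PipelineConfig, ensembles: dict[str, Ensemble],
                  tables: dict[str, descriptors.DescriptorTable],
                  outdir: Path) -> list[compare.ComparisonResult]:
    results = []
    wt_table = tables["WT"]
    for name in config.variants:
        res = compare.compare_to_wildtype(
            tables[name], wt_table, ensembles[name],
            bins=config.histogram_bins,
            n_pairs=config.heterogeneity_pairs,
            seed=variant_seed(config.base_seed, name),
        )
        results.append(res)
    compare.write_report(results, outdir / "comparison")
    return results


def assay_stage(config: PipelineConfig, outdir: Path) -> None:
    assay_dir = outdir / "assay"
    assay_dir.mkdir(parents=True, exist_ok=True)
    plate = assay.simulate_plate(noise_sd=config.plate_noise_sd,
                                 n_rep=config.plate_replicates,
                                 seed=config.base_seed)
    plate.write_csv(assay_dir / "plate.csv")
    assay.summarize_plate(plate).to_csv(assay_dir / "plate_summary.csv")
    assay.anova_vs_control(plate, config.anova_control,
                           alpha=config.anova_alpha).to_csv(
        assay_dir / "plate_anova.csv")


def nps_stage(config: PipelineConfig, outdir: Path) -> None:
    nps_dir = outdir / "nps"
    nps_dir.mkdir(parents=True, exist_ok=True)
    for scenario in assay.NPS_SCENARIOS:
        trace = assay.simulate_nps_trace(scenario, seed=config.base_seed,
                                         noise_sd=config.nps_noise_sd)
        trace.write_csv(nps_dir / f"{scenario}.csv")
        assay.analyze_trace(trace).to_csv(nps_dir / f"{scenario}_windows.csv")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages into ``config.outdir`` and write a manifest.

    A failing stage aborts with :class:`PipelineError` naming the stage;
    outputs of completed stages are kept.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest = {
        "config_hash": config.content_hash(),
        "base_seed": config.base_seed,
        "variant_seeds": {
            name: variant_seed(config.base_seed, name)
            for name in tuple(config.variants) + (EV_LABEL,)
        },
        "stages": {},
    }

    state: dict = {}

    def run_stage(name, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(config, *args, outdir)
        except Exception as exc:
            _write_manifest(outdir, manifest)
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        return result

    state["ensembles"] = run_stage("simulate", simulate_stage)
    state["tables"] = run_stage("descriptors", descriptor_stage, state["ensembles"])
    run_stage("compare", compare_stage, state["ensembles"], state["tables"])
    run_stage("assay", lambda cfg, out: assay_stage(cfg, out))
    run_stage("nps", lambda cfg, out: nps_stage(cfg, out))

    manifest["files"] = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        and p.name != "manifest.json"
    )
    _write_manifest(outdir, manifest)
    return outdir


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
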