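"""End-to-end pipeline: scan -> LD block -> neutrality tests -> 2D SFS ->
forward simulation -> haplotype census, with a reproducible run manifest."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .ancient import haplotype_census
from .core_stats import fay_wu_h_norm, find_ld_block, fst_scan, tajimas_d
from .dualsim import (
    DemographyParams,
    SelectionParams,
    TrajectoryBatch,
    ks_compare,
    simulate_batch,
    weighted_fst_hist,
)
from .sfs2d import build_phi2d, iav_stats, iav_null_summaries, null_distribution, sweep_test
from .synth import (
    CoalescentConfig,
    SweepFixtureConfig,
    make_sweep_fixture,
    read_vcf,
    surrogate_empirical_fst,
)
from .types import HaplotypeMatrix, Region

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    vcf: str | None = None
    panel: str | None = None  # TSV sample_id<TAB>pop
    core_site: str = "core"
    region: str | None = None  # chrom:start-end
    maf_min: float = 0.05
    dprime_min: float = 0.98
    r2_min: float = 0.75
    q_threshold: float = 0.05
    null_reps: int = 200
    sim_reps: int = 200
    seed: int = 0
    outdir: str = "pipeline_out"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _load_panel(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def _write_tsv(df: pd.DataFrame, path: str, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={cfg.seed} config_hash={cfg.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage on the given VCF (or a synthetic fixture when no
    input is provided) and write one TSV per stage plus a manifest."""
    os.makedirs(cfg.outdir, exist_ok=True)
    results: dict = {}

    # -- ingest -------------------------------------------------------------
    if cfg.vcf is not None:
        if not os.path.exists(cfg.vcf):
            raise PipelineError("ingest", f"input VCF not found: {cfg.vcf}")
        panel = _load_panel(cfg.panel) if cfg.panel else None
        matrix = read_vcf(cfg.vcf, panel)
    else:
        fixture, truth = make_sweep_fixture(
            SweepFixtureConfig(seed=cfg.seed, diversity_scalars=(0.2, 0.2))
        )
        # synthetic mode: split the fixture into two pseudo-populations
        labels = np.array(
            ["popA" if i % 2 == 0 else "popB" for i in range(fixture.n_haplotypes)],
            dtype=object,
        )
        matrix = HaplotypeMatrix(
            fixture.alleles, fixture.positions, fixture.site_ids, labels, fixture.chrom
        )
        results["truth"] = truth
    if cfg.region is not None:
        matrix = matrix.subset_region(Region.parse(cfg.region))
    pops = sorted(set(matrix.pop_labels))
    if len(pops) < 2:
        raise PipelineError("ingest", "need >= 2 populations in the panel")
    pop_a, pop_b = pops[0], pops[1]
    ma, mb = matrix.subset_population(pop_a), matrix.subset_population(pop_b)

    # -- stage 1: FST scan --------------------------------------------------
    try:
        seg = np.flatnonzero(matrix.segregating_mask())
        ma_s, mb_s = ma.take_sites(seg), mb.take_sites(seg)
        scan = fst_scan(ma_s, mb_s)
        _write_tsv(scan, os.path.join(cfg.outdir, "fst_scan.tsv"), cfg)
        results["fst_scan"] = scan
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fst_scan", str(exc)) from exc

    # -- stage 2: LD block --------------------------------------------------
    try:
        block = find_ld_block(matrix, cfg.core_site, cfg.dprime_min, cfg.maf_min)
        results["ld_block"] = block
        _write_tsv(pd.DataFrame([block.__dict__]), os.path.join(cfg.outdir, "ld_block.tsv"), cfg)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("ld_block", str(exc)) from exc

    # -- stage 3: SFS neutrality tests -------------------------------------
    try:
        span = Region(matrix.chrom, block.start_bp, block.end_bp)
        rows = []
        for name, sub in ((pop_a, ma), (pop_b, mb)):
            td = tajimas_d(sub, span, n_reps=cfg.null_reps, seed=cfg.seed)
            fw = fay_wu_h_norm(sub, span, n_reps=cfg.null_reps, seed=cfg.seed + 1)
            rows.append({"pop": name, "statistic": "tajimas_d", "value": td.statistic, "p": td.p_value})
            rows.append({"pop": name, "statistic": "fay_wu_h", "value": fw.statistic, "p": fw.p_value})
        sfs_tests = pd.DataFrame(rows)
        _write_tsv(sfs_tests, os.path.join(cfg.outdir, "sfs_tests.tsv"), cfg)
        results["sfs_tests"] = sfs_tests
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("sfs_tests", str(exc)) from exc

    # -- stage 4: 2D SFS sweep test ----------------------------------------
    try:
        phi = build_phi2d(matrix, cfg.core_site, 1, span)
        summary = iav_stats(phi)
        demog = CoalescentConfig(n=matrix.n_haplotypes, theta=max(phi.n_region_sites / 3.0, 2.0))
        core_freq = float(phi.n_D / matrix.n_haplotypes)
        summaries = iav_null_summaries(demog, core_freq, cfg.null_reps, seed=cfg.seed)
        nulls = {
            s: null_distribution(
                s, demog, matrix.n_haplotypes, demog.theta, core_freq,
                n_reps=cfg.null_reps, seed=cfg.seed, allow_few_reps=True,
                summaries=summaries,
            )
            for s in ("F_c", "G_c0", "L_c0")
        }
        test = sweep_test(summary, nulls, q_threshold=cfg.q_threshold)
        tbl = pd.DataFrame(
            [
                {
                    "statistic": s,
                    "value": getattr(summary, s),
                    "p": test["p_values"][s],
                    "q": test["q_values"][s],
                }
                for s in ("F_c", "G_c0", "L_c0")
            ]
            + [
                {"statistic": "G_star_c0", "value": summary.G_star_c0, "p": np.nan, "q": np.nan},
                {"statistic": "gamma_star_10", "value": summary.gamma_star_10, "p": np.nan, "q": np.nan},
                {"statistic": "i_max", "value": summary.i_max, "p": np.nan, "q": np.nan},
                {"statistic": "i_star_max", "value": summary.i_star_max, "p": np.nan, "q": np.nan},
            ]
        )
        _write_tsv(tbl, os.path.join(cfg.outdir, "sfs2d.tsv"), cfg)
        results["sfs2d"] = {"summary": summary, "test": test}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("sfs2d", str(exc)) from exc

    # -- stage 5: forward simulation ---------------------------------------
    try:
        rng = np.random.default_rng(cfg.seed)
        params = DemographyParams(t1=875, r=0.4, N_JMN=1000, N_A_CNT=4000)
        batch = simulate_batch(params, SelectionParams(0.0), [0.5], cfg.sim_reps, rng)
        sim_fst = weighted_fst_hist(batch, p_weights=(1.0,), f_grid=(0.5,), total=2000, rng=rng)
        emp = surrogate_empirical_fst(2000, seed=cfg.seed)
        ks = ks_compare(sim_fst, emp)
        sim_tbl = pd.DataFrame([{**params.__dict__, "ks_D": ks["D"], "ks_p": ks["p"]}])
        _write_tsv(sim_tbl, os.path.join(cfg.outdir, "simulation.tsv"), cfg)
        results["simulation"] = ks
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulation", str(exc)) from exc

    # -- stage 6: haplotype census -----------------------------------------
    try:
        census = haplotype_census(matrix, cfg.core_site)
        _write_tsv(census, os.path.join(cfg.outdir, "census.tsv"), cfg)
        results["census"] = census
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("census", str(exc)) from exc

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "stages": ["fst_scan", "ld_block", "sfs_tests", "sfs2d", "simulation", "census"],
    }
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
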