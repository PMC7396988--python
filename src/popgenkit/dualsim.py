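"""Forward Wright-Fisher simulator of a two-population admixture demography.

An ancestral population splits into an isolated island lineage (JMN) and a
continental lineage (A_CNT).  After ``t1`` generations the island lineage
admixes into the continental immigrants with proportion ``r``, founding the
simulated JPT; the continental lineage continues as the simulated CHB.
Both then drift for ``t2`` more generations.  The model is haploid, has no
migration, and tracks one biallelic site (T/C); selection, when enabled,
favors the C allele on the continental/CHB lineage for the admixture
generation plus ``t2`` (126 generations at the default ``t2`` = 125).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DemographyParams",
    "SelectionParams",
    "GridConfig",
    "TrajectoryBatch",
    "SuccessCriteria",
    "wf_step",
    "selection_adjust",
    "simulate_trajectory",
    "simulate_batch",
    "simulate_grid",
    "weighted_fst_hist",
    "ks_compare",
    "count_success_cases",
    "hudson_fst_from_freqs",
    "DEFAULT_P_WEIGHTS",
]

# empirical stratum weights for initial frequencies 0.1..0.9
DEFAULT_P_WEIGHTS = (0.5589, 0.0984, 0.0734, 0.0623, 0.0494, 0.0436, 0.0360, 0.0342, 0.0438)
DEFAULT_F_GRID = tuple(round(0.1 * i, 1) for i in range(1, 10))


@dataclass(frozen=True)
class DemographyParams:
    t1: int
    r: float
    N_JMN: int
    N_A_CNT: int
    t2: int = 125
    N_simJPT: int = 12_824
    N_simCHB: int = 29_204
    generation_years: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.r <= 1.0:
            raise ValueError("admixture proportion r must be in (0, 1]")
        for nm in ("N_JMN", "N_A_CNT", "N_simJPT", "N_simCHB"):
            if getattr(self, nm) < 2:
                raise ValueError(f"{nm} must be >= 2")
        if self.N_JMN > self.N_A_CNT:
            raise ValueError("N_JMN must be <= N_A_CNT")


@dataclass(frozen=True)
class SelectionParams:
    scaled: float = 0.0  # 2 * N_simCHB * s
    N_ref: int = 29_204

    @property
    def s(self) -> float:
        return self.scaled / (2.0 * self.N_ref)


@dataclass(frozen=True)
class GridConfig:
    t1_set: tuple = (875, 1125, 1375, 1875, 2375)
    r_set: tuple = (0.4, 0.2, 0.1)
    n_jmn_set: tuple = (500, 1000, 2000, 4000, 8000, 10_000, 12_500, 15_000)
    n_acnt_set: tuple = (1000, 2000, 4000, 8000, 16_000, 25_000, 30_000)
    reps_per_freq: int = 10_000
    f_grid: tuple = DEFAULT_F_GRID
    p_weights: tuple = DEFAULT_P_WEIGHTS

    def combinations(self) -> list[DemographyParams]:
        """Enumerate the grid under the N_JMN <= N_A_CNT constraint."""
        out = []
        for t1, r, nj, na in product(self.t1_set, self.r_set, self.n_jmn_set, self.n_acnt_set):
            if nj <= na:
                out.append(DemographyParams(t1=t1, r=r, N_JMN=nj, N_A_CNT=na))
        return out


@dataclass
class TrajectoryBatch:
    params: DemographyParams
    selection: SelectionParams
    f_i: np.ndarray  # initial frequency per replicate
    jmn_final: np.ndarray  # T frequency in JMN at the last pre-admixture generation
    acnt_final: np.ndarray
    jpt_final: np.ndarray
    chb_final: np.ndarray
    fst: np.ndarray  # Hudson FST, negative clamped to 0, NaN when excluded
    excluded: np.ndarray  # fixed-in-both before or after admixture


@dataclass(frozen=True)
class SuccessCriteria:
    fst_min: float = 0.2547
    t_freq_min: float = 0.62


# ---------------------------------------------------------------------------
# elementary steps
# ---------------------------------------------------------------------------

def selection_adjust(p, s_on_C):
    """Deterministic selection update of the T frequency when C (the other
    allele) has fitness 1 + s: p* = p / (p + (1-p)(1+s))."""
    p = np.asarray(p, dtype=float)
    return p / (p + (1.0 - p) * (1.0 + s_on_C))


def wf_step(freq_T, N: int, s_on_C: float, rng: np.random.Generator):
    """One haploid Wright-Fisher generation; 0 and 1 are absorbing."""
    if N < 2:
        raise ValueError("population size must be >= 2")
    p = np.asarray(freq_T, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    out = p.copy()
    live = (p > 0.0) & (p < 1.0)
    if live.any():
        pstar = selection_adjust(p[live], s_on_C) if s_on_C != 0.0 else p[live]
        out[live] = rng.binomial(N, pstar) / N
    return float(out[0]) if scalar else out


def _drift(p: np.ndarray, N: int, gens: int, s: float, rng: np.random.Generator) -> np.ndarray:
    for _ in range(gens):
        p = wf_step(p, N, s, rng)
    return p


def hudson_fst_from_freqs(p1, p2, n1: int, n2: int, clamp: bool = True):
    """Vectorized Hudson FST from two frequency arrays; NaN when undefined."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    if clamp:
        fst = np.where(fst < 0, 0.0, fst)
    return fst


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def simulate_trajectory(
    params: DemographyParams,
    sel: SelectionParams,
    f_i: float,
    rng: np.random.Generator,
    record_path: bool = False,
) -> dict:
    """One replicate of the dual-structure model.

    Returns final frequencies (and full paths when ``record_path``).
    Selection acts on the continental lineage starting at the admixture
    generation, i.e. for t2 + 1 generations.
    """
    s = sel.s
    path_jmn, path_acnt, path_jpt, path_chb = [], [], [], []
    p_jmn = np.float64(f_i)
    p_acnt = np.float64(f_i)
    for _ in range(params.t1):
        p_jmn = wf_step(p_jmn, params.N_JMN, 0.0, rng)
        p_acnt = wf_step(p_acnt, params.N_A_CNT, 0.0, rng)
        if record_path:
            path_jmn.append(float(p_jmn))
            path_acnt.append(float(p_acnt))
    jmn_final, acnt_final = float(p_jmn), float(p_acnt)
    # admixture generation: JPT founded as the mixture; selection round one
    # applies on the continental side at this generation
    p_jpt = params.r * jmn_final + (1 - params.r) * acnt_final
    p_chb = wf_step(acnt_final, params.N_simCHB, s, rng)
    for _ in range(params.t2):
        p_jpt = wf_step(p_jpt, params.N_simJPT, 0.0, rng)
        p_chb = wf_step(p_chb, params.N_simCHB, s, rng)
        if record_path:
            path_jpt.append(float(p_jpt))
            path_chb.append(float(p_chb))
    out = {
        "jmn_final": jmn_final,
        "acnt_final": acnt_final,
        "jpt_initial": params.r * jmn_final + (1 - params.r) * acnt_final,
        "jpt_final": float(p_jpt),
        "chb_final": float(p_chb),
    }
    if record_path:
        out["paths"] = {
            "jmn": path_jmn,
            "acnt": path_acnt,
            "jpt": path_jpt,
            "chb": path_chb,
        }
    return out


def simulate_batch(
    params: DemographyParams,
    sel: SelectionParams,
    f_grid,
    reps_per_freq: int,
    rng: np.random.Generator,
) -> TrajectoryBatch:
    """Vectorized batch of replicates across the initial-frequency grid."""
    f_grid = np.asarray(f_grid, dtype=float)
    f_i = np.repeat(f_grid, reps_per_freq)
    n = f_i.size
    s = sel.s
    p_jmn = f_i.copy()
    p_acnt = f_i.copy()
    for _ in range(params.t1):
        p_jmn = wf_step(p_jmn, params.N_JMN, 0.0, rng)
        p_acnt = wf_step(p_acnt, params.N_A_CNT, 0.0, rng)
    jmn_final = p_jmn.copy()
    acnt_final = p_acnt.copy()
    pre_fixed = ((jmn_final == 0.0) & (acnt_final == 0.0)) | (
        (jmn_final == 1.0) & (acnt_final == 1.0)
    )
    p_jpt = params.r * jmn_final + (1 - params.r) * acnt_final
    p_chb = wf_step(acnt_final, params.N_simCHB, s, rng)
    for _ in range(params.t2):
        p_jpt = wf_step(p_jpt, params.N_simJPT, 0.0, rng)
        p_chb = wf_step(p_chb, params.N_simCHB, s, rng)
    post_fixed = ((p_jpt == 0.0) & (p_chb == 0.0)) | ((p_jpt == 1.0) & (p_chb == 1.0))
    excluded = pre_fixed | post_fixed
    fst = hudson_fst_from_freqs(p_jpt, p_chb, params.N_simJPT, params.N_simCHB)
    fst[excluded] = np.nan
    return TrajectoryBatch(
        params=params,
        selection=sel,
        f_i=f_i,
        jmn_final=jmn_final,
        acnt_final=acnt_final,
        jpt_final=p_jpt,
        chb_final=p_chb,
        fst=fst,
        excluded=excluded,
    )


def simulate_grid(
    grid: GridConfig,
    sel: SelectionParams = SelectionParams(),
    seed: int = 0,
    combos: list[DemographyParams] | None = None,
) -> list[TrajectoryBatch]:
    """Simulate every grid combination with deterministic per-combination
    child RNG streams (grid subsets reproduce under the same root seed)."""
    if combos is None:
        combos = grid.combinations()
    root = np.random.SeedSequence(seed)
    batches = []
    for k, params in enumerate(combos):
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(k,))
        rng = np.random.default_rng(child)
        batches.append(simulate_batch(params, sel, grid.f_grid, grid.reps_per_freq, rng))
    return batches


# ---------------------------------------------------------------------------
# distribution comparison and success counting
# ---------------------------------------------------------------------------

def weighted_fst_hist(
    batch: TrajectoryBatch,
    p_weights=DEFAULT_P_WEIGHTS,
    f_grid=DEFAULT_F_GRID,
    total: int = 90_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Weighted FST sample: each initial-frequency stratum is resampled in
    proportion to its weight (classical two-sample KS has no weighted form,
    so weighting is realized by proportional resampling)."""
    p_weights = np.asarray(p_weights, dtype=float)
    f_grid = np.asarray(f_grid, dtype=float)
    if p_weights.size != f_grid.size:
        raise ValueError("weights and f_i grid lengths differ")
    if abs(p_weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    if rng is None:
        rng = np.random.default_rng(0)
    out = []
    for f, w in zip(f_grid, p_weights):
        vals = batch.fst[(batch.f_i == f) & ~batch.excluded]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        k = int(round(w * total))
        if k > 0:
            out.append(rng.choice(vals, size=k, replace=True))
    if not out:
        return np.empty(0)
    return np.concatenate(out)


def ks_compare(sim_sample, empirical_sample, alpha: float = 0.05) -> dict:
    """Two-sample Kolmogorov-Smirnov comparison with a pass flag."""
    sim_sample = np.asarray(sim_sample, dtype=float)
    empirical_sample = np.asarray(empirical_sample, dtype=float)
    if sim_sample.size == 0 or empirical_sample.size == 0:
        raise ValueError("empty sample")
    res = sps.ks_2samp(sim_sample, empirical_sample, method="asymp")
    return {"D": float(res.statistic), "p": float(res.pvalue), "pass": res.pvalue >= alpha}


def count_success_cases(
    batches: list[TrajectoryBatch],
    criteria: SuccessCriteria = SuccessCriteria(),
) -> pd.DataFrame:
    """Per-combination count of replicates attaining high FST and high
    T frequency in JPT, with T_JPT > T_CHB and no allele fixed in either
    final population."""
    rows = []
    for b in batches:
        ok = (
            ~b.excluded
            & ~np.isnan(b.fst)
            & (b.fst > criteria.fst_min)
            & (b.jpt_final > criteria.t_freq_min)
            & (b.jpt_final > b.chb_final)
            & (b.jpt_final > 0.0)
            & (b.jpt_final < 1.0)
            & (b.chb_final > 0.0)
            & (b.chb_final < 1.0)
        )
        succ = np.flatnonzero(ok)
        rows.append(
            {
                "t1": b.params.t1,
                "r": b.params.r,
                "N_JMN": b.params.N_JMN,
                "N_A_CNT": b.params.N_A_CNT,
                "scaled_s": b.selection.scaled,
                "n_success": int(ok.sum()),
                "n_success_cells": int(np.unique(b.f_i[succ]).size),
                "median_jmn_final_success": float(np.median(b.jmn_final[succ]))
                if succ.size
                else math.nan,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_combinations_with_success"] = int((df["n_success"] > 0).sum())
    return df
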