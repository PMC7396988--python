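"""Haplotype- and frequency-based population-genetic statistics.

Implements the Hudson FST estimator (Bhatia et al. 2013 form), nucleotide
diversity with a Nei (1987)-style sampling variance, Tajima's D and the
normalized Fay & Wu's H with coalescent-simulated null p-values, haplotype
homozygosity (H12), EHH, nSL, PBS, pairwise LD (D'/r2), D'-chained LD-block
detection, and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import (
    DiversityResult,
    FstRecord,
    HaplotypeMatrix,
    LDBlock,
    NeutralityTestResult,
    Region,
    SiteFreq,
)

__all__ = [
    "hudson_fst",
    "fst_scan",
    "block_fst",
    "nucleotide_diversity",
    "compare_pi_ztest",
    "tajimas_d",
    "fay_wu_h_norm",
    "h12",
    "h12_scan",
    "ehh",
    "nsl",
    "pbs",
    "d_prime_r2",
    "find_ld_block",
    "select_core_region",
    "bh_fdr",
]


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

def hudson_fst(a: SiteFreq, b: SiteFreq, clamp: bool = False, site_id: str = "") -> FstRecord:
    """Hudson's FST for one site from two population samples.

    Uses the ratio-of-estimates form
    ``[(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)] / [p1(1-p2) + p2(1-p1)]``
    with haplotype counts as sample sizes.  A zero denominator (both samples
    monomorphic for the same allele) yields an undefined record that scans
    must exclude.  With ``clamp`` a negative estimate is reported as 0; the
    raw value is kept alongside.
    """
    p1, p2 = a.freq, b.freq
    n1, n2 = a.n, b.n
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den == 0.0:
        return FstRecord(site_id=site_id, fst=math.nan, raw=math.nan, defined=False)
    raw = num / den
    val = raw
    clamped = False
    if clamp and raw < 0.0:
        val, clamped = 0.0, True
    return FstRecord(site_id=site_id, fst=val, raw=raw, clamped=clamped)


def fst_scan(
    matrix_a: HaplotypeMatrix,
    matrix_b: HaplotypeMatrix,
    exclusions: list[Region] | None = None,
    clamp: bool = True,
) -> pd.DataFrame:
    """Per-site Hudson FST between two cohorts sharing a site list.

    Sites falling in any exclusion region (e.g. the MHC interval) are
    dropped.  Returns a table with columns ``site_id, pos, fst, raw,
    defined`` plus an empirical ``percentile`` among defined sites.
    """
    if matrix_a.site_ids != matrix_b.site_ids or not np.array_equal(
        matrix_a.positions, matrix_b.positions
    ):
        raise ValueError("site lists of the two matrices do not align")
    keep = np.ones(matrix_a.n_sites, dtype=bool)
    for reg in exclusions or []:
        if reg.chrom == matrix_a.chrom:
            keep &= ~((matrix_a.positions >= reg.start) & (matrix_a.positions <= reg.end))
    idx = np.flatnonzero(keep)
    n1, n2 = matrix_a.n_haplotypes, matrix_b.n_haplotypes
    c1 = matrix_a.alleles[:, idx].sum(axis=0)
    c2 = matrix_b.alleles[:, idx].sum(axis=0)
    p1, p2 = c1 / n1, c2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    defined = den > 0
    raw = np.full(idx.size, np.nan)
    raw[defined] = num[defined] / den[defined]
    fst = np.where(defined & (raw < 0) if clamp else np.zeros_like(defined), 0.0, raw)
    df = pd.DataFrame(
        {
            "site_id": [matrix_a.site_ids[i] for i in idx],
            "pos": matrix_a.positions[idx],
            "fst": fst,
            "raw": raw,
            "defined": defined,
        }
    )
    ranks = sps.rankdata(df.loc[defined, "fst"], method="average")
    pct = np.full(len(df), np.nan)
    pct[np.flatnonzero(defined)] = 100.0 * ranks / defined.sum()
    df["percentile"] = pct
    return df


def block_fst(scan: pd.DataFrame, window_bp: int, start: int | None = None) -> pd.DataFrame:
    """Mean FST in non-overlapping fixed-width windows, ranked descending.

    Windows with no defined site get NaN and no rank.
    """
    if not scan["pos"].is_monotonic_increasing:
        raise ValueError("scan must be sorted by position")
    if start is None:
        start = int(scan["pos"].iloc[0])
    win = ((scan["pos"] - start) // window_bp).astype(int)
    last = int((scan["pos"].iloc[-1] - start) // window_bp)
    rows = []
    for w in range(last + 1):
        sub = scan[(win == w) & scan["defined"]]
        mean = float(sub["fst"].mean()) if len(sub) else math.nan
        rows.append(
            {
                "window": w,
                "start_bp": start + w * window_bp,
                "end_bp": start + (w + 1) * window_bp - 1,
                "n_sites": len(sub),
                "mean_fst": mean,
            }
        )
    df = pd.DataFrame(rows)
    df["rank"] = df["mean_fst"].rank(ascending=False, method="min")
    return df


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def nucleotide_diversity(m: HaplotypeMatrix, span: Region | None = None) -> DiversityResult:
    """Per-site nucleotide diversity over a span.

    pi = sum_sites 2 p (1-p) n/(n-1) / L with L the number of sites in the
    span; identical to mean pairwise Hamming distance per site.  The
    sampling variance follows Nei (1987, eq. 10.7).
    """
    if span is not None:
        m = m.subset_region(span)
    n, L = m.n_haplotypes, m.n_sites
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    if L == 0:
        raise ValueError("span contains no sites")
    p = m.derived_freqs()
    pi = float((2.0 * p * (1.0 - p) * n / (n - 1)).sum() / L)
    var = (n + 1) / (3 * (n - 1) * L) * pi + 2 * (n**2 + n + 3) / (9 * n * (n - 1)) * pi**2
    return DiversityResult(pi=pi, var_pi=float(var), n=n, L=L)


def compare_pi_ztest(a: DiversityResult, b: DiversityResult) -> tuple[float, float]:
    """Two-sided z-test for a difference in nucleotide diversity."""
    se2 = a.var_pi + b.var_pi
    diff = a.pi - b.pi
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        raise ValueError("zero combined variance with unequal pi")
    z = diff / math.sqrt(se2)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# SFS-based neutrality tests
# ---------------------------------------------------------------------------

def _harmonics(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    return float((1.0 / i).sum()), float((1.0 / i**2).sum())


def _tajima_constants(n: int) -> tuple[float, float, float]:
    a1, a2 = _harmonics(n)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def _sfs_counts(m: HaplotypeMatrix) -> np.ndarray:
    """Unfolded SFS: S_i = number of sites with derived count i, i=1..n-1."""
    c = m.derived_counts()
    c = c[(c > 0) & (c < m.n_haplotypes)]
    return np.bincount(c, minlength=m.n_haplotypes)[1 : m.n_haplotypes]


def _tajimas_d_from_sfs(sfs: np.ndarray, n: int) -> float:
    S = int(sfs.sum())
    if S == 0:
        return math.nan
    i = np.arange(1, n)
    theta_pi = float((2.0 * i * (n - i) * sfs).sum() / (n * (n - 1)))
    a1, e1, e2 = _tajima_constants(n)
    return (theta_pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def _fay_wu_h_from_sfs(sfs: np.ndarray, n: int) -> float:
    """Normalized H of Zeng et al. (2006): (theta_pi - theta_L)/sd."""
    S = int(sfs.sum())
    if S == 0:
        return math.nan
    i = np.arange(1, n)
    theta_pi = float((2.0 * i * (n - i) * sfs).sum() / (n * (n - 1)))
    theta_l = float((i * sfs).sum() / (n - 1))
    a1, b_n = _harmonics(n)
    b_n1 = b_n + 1.0 / n**2  # sum_{i=1}^{n} 1/i^2
    theta_w = S / a1
    theta2 = S * (S - 1) / (a1**2 + b_n)
    var = (
        theta_w * (n - 2) / (6 * (n - 1))
        + theta2
        * (18 * n**2 * (3 * n + 2) * b_n1 - (88 * n**3 + 9 * n**2 - 13 * n + 6))
        / (9 * n * (n - 1) ** 2)
    )
    return (theta_pi - theta_l) / math.sqrt(var)


def _coalescent_null_stats(
    n: int,
    S: int,
    n_reps: int,
    stat_fn,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null distribution of an SFS statistic under the standard coalescent,
    conditioned on the observed number of segregating sites.

    For each replicate a Kingman genealogy is drawn and S mutations are
    placed multinomially on branches proportional to length; the statistic
    is computed from the resulting unfolded SFS.
    """
    out = np.empty(n_reps)
    for r in range(n_reps):
        # simulate branch (length, subtended-leaf-count) pairs
        lengths: list[float] = []
        leaves: list[int] = []
        active = [1] * n  # leaf counts of active lineages
        born = [0.0] * n  # birth time of each active lineage
        t = 0.0
        k = n
        while k > 1:
            t += rng.exponential(2.0 / (k * (k - 1)))
            i, j = rng.choice(k, size=2, replace=False)
            i, j = (int(i), int(j)) if i < j else (int(j), int(i))
            for x in (j, i):  # j first: higher index
                lengths.append(t - born[x])
                leaves.append(active[x])
            merged = active[i] + active[j]
            for x in (j, i):
                del active[x], born[x]
            active.append(merged)
            born.append(t)
            k -= 1
        lengths_a = np.asarray(lengths)
        leaves_a = np.asarray(leaves)
        probs = lengths_a / lengths_a.sum()
        muts = rng.multinomial(S, probs)
        sfs = np.bincount(leaves_a, weights=muts, minlength=n)[1:n]
        out[r] = stat_fn(sfs, n)
    return out


def _null_p_value(stat: float, null: np.ndarray, tail: str) -> float:
    null = null[~np.isnan(null)]
    m = null.size
    if tail == "low":
        return float((1 + (null <= stat).sum()) / (m + 1))
    if tail == "high":
        return float((1 + (null >= stat).sum()) / (m + 1))
    lo = (1 + (null <= stat).sum()) / (m + 1)
    hi = (1 + (null >= stat).sum()) / (m + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def tajimas_d(
    m: HaplotypeMatrix,
    span: Region | None = None,
    n_reps: int = 10_000,
    seed: int | None = None,
    method: str = "coalescent",
) -> NeutralityTestResult:
    """Tajima's D with a two-sided p-value.

    ``method='coalescent'`` draws the null from fixed-S coalescent
    simulation; ``method='beta'`` uses the beta-distribution approximation
    of Tajima (1989).
    """
    if span is not None:
        m = m.subset_region(span)
    n = m.n_haplotypes
    if n < 4:
        raise ValueError("need >= 4 haplotypes")
    sfs = _sfs_counts(m)
    S = int(sfs.sum())
    if S == 0:
        return NeutralityTestResult(statistic=math.nan, p_value=math.nan, method="tajimas_d")
    d = _tajimas_d_from_sfs(sfs, n)
    if method == "beta":
        p = _beta_p_value(d, n)
    else:
        rng = np.random.default_rng(seed)
        null = _coalescent_null_stats(n, S, n_reps, _tajimas_d_from_sfs, rng)
        p = _null_p_value(d, null, "two")
    return NeutralityTestResult(statistic=float(d), p_value=p, method="tajimas_d")


def _beta_p_value(d: float, n: int) -> float:
    # Tajima (1989): D rescaled onto a beta over [Dmin, Dmax]
    a1, _ = _harmonics(n)
    dmin = (2 / n - 1 / a1) / _tajima_constants(n)[2] ** 0.5
    dmax = ((n + 1) / (2 * n) - 1 / a1) / _tajima_constants(n)[2] ** 0.5
    rng_w = dmax - dmin
    alpha = -(1 + dmin * dmax) * dmax / rng_w
    beta = (1 + dmin * dmax) * dmin / rng_w
    # two-sided from the CDF of the scaled beta
    x = (d - dmin) / rng_w
    x = min(max(x, 0.0), 1.0)
    cdf = sps.beta.cdf(x, beta, alpha)
    return float(min(1.0, 2 * min(cdf, 1 - cdf)))


def fay_wu_h_norm(
    m: HaplotypeMatrix,
    span: Region | None = None,
    n_reps: int = 10_000,
    seed: int | None = None,
) -> NeutralityTestResult:
    """Normalized Fay & Wu's H (Zeng et al. 2006) with a one-sided (low
    tail: excess of high-frequency derived alleles) coalescent p-value."""
    if span is not None:
        m = m.subset_region(span)
    n = m.n_haplotypes
    if n < 4:
        raise ValueError("need >= 4 haplotypes")
    sfs = _sfs_counts(m)
    S = int(sfs.sum())
    if S == 0:
        return NeutralityTestResult(statistic=math.nan, p_value=math.nan, method="fay_wu_h")
    h = _fay_wu_h_from_sfs(sfs, n)
    rng = np.random.default_rng(seed)
    null = _coalescent_null_stats(n, S, n_reps, _fay_wu_h_from_sfs, rng)
    p = _null_p_value(h, null, "low")
    return NeutralityTestResult(statistic=float(h), p_value=p, method="fay_wu_h")


# ---------------------------------------------------------------------------
# haplotype homozygosity
# ---------------------------------------------------------------------------

def _hap_class_freqs(alleles: np.ndarray) -> np.ndarray:
    """Frequencies of distinct haplotype sequences, descending."""
    _, counts = np.unique(alleles, axis=0, return_counts=True)
    freqs = np.sort(counts / alleles.shape[0])[::-1]
    return freqs


def h12(window: HaplotypeMatrix) -> float:
    """Haplotype homozygosity with the two most common classes pooled."""
    if window.n_haplotypes == 0:
        raise ValueError("empty window")
    f = _hap_class_freqs(window.alleles)
    if f.size == 1:
        return 1.0
    return float((f[0] + f[1]) ** 2 + (f[2:] ** 2).sum())


def h12_scan(m: HaplotypeMatrix, window_snps: int, step: int = 1) -> pd.DataFrame:
    """Sliding-window H12 track with empirical mean and 95% band."""
    if step <= 0:
        raise ValueError("step must be positive")
    if window_snps > m.n_sites:
        raise ValueError("window larger than matrix")
    starts = range(0, m.n_sites - window_snps + 1, step)
    rows = []
    for s in starts:
        sub = m.alleles[:, s : s + window_snps]
        f = _hap_class_freqs(sub)
        val = 1.0 if f.size == 1 else float((f[0] + f[1]) ** 2 + (f[2:] ** 2).sum())
        rows.append(
            {
                "start_index": s,
                "center_bp": int(m.positions[s : s + window_snps].mean()),
                "h12": val,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["mean"] = float(df["h12"].mean())
    df.attrs["lower95"] = float(np.percentile(df["h12"], 2.5))
    df.attrs["upper95"] = float(np.percentile(df["h12"], 97.5))
    return df


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------

def ehh(
    m: HaplotypeMatrix,
    core_site: str,
    core_allele: int,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """EHH decay away from a core site for carriers of one core allele.

    Sites with MAF below ``maf_min`` are removed first (the core site is
    always retained).  EHH(x) is the probability that two random carriers
    are identical at every retained site between the core and x, computed
    as sum_k C(n_k,2)/C(n,2) over extended-haplotype classes.
    """
    core_idx_orig = m.site_index(core_site)
    freqs = m.derived_freqs()
    maf = np.minimum(freqs, 1 - freqs)
    keep = (maf >= maf_min) | (np.arange(m.n_sites) == core_idx_orig)
    sub = m.take_sites(np.flatnonzero(keep))
    core_idx = sub.site_ids.index(core_site)
    carriers = np.flatnonzero(sub.alleles[:, core_idx] == core_allele)
    n = carriers.size
    if n < 2:
        raise ValueError("core allele carried by fewer than 2 haplotypes")
    h = sub.alleles[carriers, :]
    denom = n * (n - 1) / 2
    rows = []
    core_pos = int(sub.positions[core_idx])
    for direction, order in (("right", range(core_idx, sub.n_sites)), ("left", range(core_idx, -1, -1))):
        # group haplotypes by prefix extending outward
        groups = [np.arange(n)]
        for j in order:
            new_groups = []
            for g in groups:
                vals = h[g, j]
                for v in (0, 1):
                    sel = g[vals == v]
                    if sel.size:
                        new_groups.append(sel)
            groups = new_groups
            hom = sum(g.size * (g.size - 1) / 2 for g in groups) / denom
            rows.append(
                {
                    "pos": int(sub.positions[j]),
                    "site_id": sub.site_ids[j],
                    "distance_bp": int(sub.positions[j]) - core_pos,
                    "site_offset": j - core_idx,
                    "direction": direction,
                    "ehh": hom,
                }
            )
    df = pd.DataFrame(rows).drop_duplicates(subset=["pos", "direction"])
    return df.sort_values(["direction", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# nSL
# ---------------------------------------------------------------------------

def _pair_sl(h: np.ndarray, focal: int, cap: int | None) -> float:
    """Mean, over haplotype pairs, of the number of consecutive segregating
    sites (containing the focal site) over which the pair is identical."""
    n, S = h.shape
    total = 0.0
    npairs = 0
    for a in range(n):
        for b in range(a + 1, n):
            eq = h[a] == h[b]
            if not eq[focal]:
                length = 0
            else:
                left = focal
                while left > 0 and eq[left - 1]:
                    left -= 1
                right = focal
                while right < S - 1 and eq[right + 1]:
                    right += 1
                length = right - left + 1
                if cap is not None and length > cap:
                    length = cap
            total += length
            npairs += 1
    return total / npairs


def nsl(
    m: HaplotypeMatrix,
    maf_min: float = 0.01,
    max_window: int | None = 100,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Per-site nSL scores, standardized within derived-frequency bins.

    The unstandardized score is ln(SL_ancestral / SL_derived); SL is the
    mean identical-tract length in segregating-site units among haplotype
    pairs within the allele class at the focal site.  ``max_window`` caps
    the tract length (in sites); ``None`` removes the cap.
    """
    freqs = m.derived_freqs()
    maf = np.minimum(freqs, 1 - freqs)
    keep = np.flatnonzero((maf >= maf_min) & m.segregating_mask())
    sub = m.take_sites(keep)
    h = sub.alleles
    n = sub.n_haplotypes
    raw = np.full(sub.n_sites, np.nan)
    for j in range(sub.n_sites):
        der = np.flatnonzero(h[:, j] == 1)
        anc = np.flatnonzero(h[:, j] == 0)
        if der.size < 2 or anc.size < 2:
            continue
        sl_d = _pair_sl(h[der], j, max_window)
        sl_a = _pair_sl(h[anc], j, max_window)
        if sl_d > 0 and sl_a > 0:
            raw[j] = math.log(sl_a / sl_d)
    df = pd.DataFrame(
        {
            "site_id": sub.site_ids,
            "pos": sub.positions,
            "derived_freq": sub.derived_freqs(),
            "nsl_raw": raw,
        }
    )
    # standardize within equal-width derived-frequency bins
    bins = np.minimum((df["derived_freq"] * n_bins).astype(int), n_bins - 1)
    std = np.full(len(df), np.nan)
    for b in range(n_bins):
        sel = (bins == b) & ~np.isnan(raw)
        if sel.sum() >= 2 and np.nanstd(raw[sel]) > 0:
            std[sel] = (raw[sel] - np.nanmean(raw[sel])) / np.nanstd(raw[sel])
        elif sel.sum() >= 1:
            std[sel] = 0.0
    df["nsl"] = std
    df["significant_05"] = np.abs(std) > 1.96
    return df


# ---------------------------------------------------------------------------
# PBS
# ---------------------------------------------------------------------------

def pbs(fst_ab: float, fst_ao: float, fst_bo: float, clamp: bool = True) -> tuple[float, float]:
    """Population branch statistics for branches a and b.

    T = -ln(1 - FST); PBS_a = (T_ab + T_ao - T_bo)/2.  FST of exactly 1
    gives an infinite branch.
    """
    for f in (fst_ab, fst_ao, fst_bo):
        if f >= 1.0:
            return math.inf, math.inf
    t_ab = -math.log(1 - max(fst_ab, 0.0))
    t_ao = -math.log(1 - max(fst_ao, 0.0))
    t_bo = -math.log(1 - max(fst_bo, 0.0))
    pa = (t_ab + t_ao - t_bo) / 2
    pb = (t_ab + t_bo - t_ao) / 2
    if clamp:
        pa, pb = max(pa, 0.0), max(pb, 0.0)
    return pa, pb


# ---------------------------------------------------------------------------
# pairwise LD, LD blocks, core region
# ---------------------------------------------------------------------------

def d_prime_r2(site_a: str, site_b: str, m: HaplotypeMatrix) -> tuple[float, float]:
    """D' and r2 between two sites from phased haplotypes."""
    ia, ib = m.site_index(site_a), m.site_index(site_b)
    return _dprime_r2_cols(m.alleles[:, ia], m.alleles[:, ib])


def _dprime_r2_cols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pa = x.mean()
    pb = y.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic site")
    pab = (x & y).mean()
    d = pab - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dprime = abs(d) / dmax if dmax > 0 else 0.0
    r2 = d**2 / (pa * (1 - pa) * pb * (1 - pb))
    return float(dprime), float(r2)


def find_ld_block(
    m: HaplotypeMatrix,
    anchor_site: str,
    dprime_min: float = 0.98,
    maf_min: float = 0.05,
) -> LDBlock:
    """Maximal run of MAF-filtered sites around the anchor in which every
    adjacent pair has D' > ``dprime_min`` (adjacent-pair chaining rule)."""
    freqs = m.derived_freqs()
    maf = np.minimum(freqs, 1 - freqs)
    anchor_orig = m.site_index(anchor_site)
    if maf[anchor_orig] < maf_min:
        raise ValueError("anchor site fails the MAF filter")
    keep = np.flatnonzero(maf >= maf_min)
    sub = m.take_sites(keep)
    a = sub.site_ids.index(anchor_site)
    lo = a
    while lo > 0:
        dp, _ = _dprime_r2_cols(sub.alleles[:, lo - 1], sub.alleles[:, lo])
        if dp > dprime_min:
            lo -= 1
        else:
            break
    hi = a
    while hi < sub.n_sites - 1:
        dp, _ = _dprime_r2_cols(sub.alleles[:, hi], sub.alleles[:, hi + 1])
        if dp > dprime_min:
            hi += 1
        else:
            break
    return LDBlock(
        start_index=int(keep[lo]),
        end_index=int(keep[hi]),
        start_bp=int(sub.positions[lo]),
        end_bp=int(sub.positions[hi]),
        n_sites=hi - lo + 1,
    )


def select_core_region(m: HaplotypeMatrix, anchor_site: str, r2_min: float = 0.75) -> Region:
    """Maximal contiguous run of sites with r2 > ``r2_min`` to the anchor,
    containing the anchor."""
    a = m.site_index(anchor_site)
    x = m.alleles[:, a]
    if x.min() == x.max():
        raise ValueError("anchor site is monomorphic")

    def ok(j: int) -> bool:
        y = m.alleles[:, j]
        if y.min() == y.max():
            return False
        _, r2 = _dprime_r2_cols(x, y)
        return r2 > r2_min

    lo = a
    while lo > 0 and ok(lo - 1):
        lo -= 1
    hi = a
    while hi < m.n_sites - 1 and ok(hi + 1):
        hi += 1
    return Region(m.chrom, int(m.positions[lo]), int(m.positions[hi]))


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m_ = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m_ / np.arange(1, m_ + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m_)
    q[order] = q_sorted
    return q
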