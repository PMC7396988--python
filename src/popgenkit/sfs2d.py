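"""Two-dimensional SFS intra-allelic-variability (IAV) sweep detection.

The 2D spectrum ``Phi[i, j]`` counts linked segregating sites whose derived
allele is carried by ``i`` haplotypes inside the focal derived-allele (D)
group and ``j`` haplotypes outside it.  Summary statistics over the
D-exclusive part of the spectrum (j = 0) measure intra-allelic variability;
low values indicate a recent sweep on the focal allele.

NOTE: the exact published formulas for F_c, G_c0, L_c0, G*_c0 and
gamma*(10) live in prior work that is not transcribed here; this module
uses documented fallback definitions (see :func:`iav_stats`) that preserve
their ranges and monotone response to sweep strength.  All formula choices
are isolated inside :func:`iav_stats` so they can be replaced wholesale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_stats import bh_fdr, nucleotide_diversity
from .types import HaplotypeMatrix, Region

__all__ = [
    "Phi2D",
    "IAVSummary",
    "NullDistribution",
    "DatingResult",
    "build_phi2d",
    "iav_stats",
    "iav_null_summaries",
    "null_distribution",
    "sweep_test",
    "classify_subhaplotypes",
    "remove_recombinants",
    "divergence_time",
    "tmrca_within",
    "sweep_mode",
]

IAV_STATS = ("F_c", "G_c0", "L_c0")


@dataclass
class Phi2D:
    matrix: np.ndarray  # (n_D + 1) x (n_O + 1)
    n_D: int
    n_O: int
    core_site: str
    core_allele: int
    n_region_sites: int  # segregating sites tallied (core excluded)
    region_bp: int = 1  # physical span of the tallied region

    def total(self) -> int:
        return int(self.matrix.sum())


@dataclass
class IAVSummary:
    F_c: float
    G_c0: float
    L_c0: float
    G_star_c0: float
    gamma_star_10: float
    i_max: int
    i_star_max: int
    degenerate: bool = False
    q_values: dict = field(default_factory=dict)


@dataclass
class NullDistribution:
    statistic: str
    values: np.ndarray  # sorted ascending
    n_reps: int
    scenario: str
    seed: int | None

    def empirical_p(
        self,
        observed: float,
        tail: str = "low",
        rng: np.random.Generator | None = None,
    ) -> float:
        """Empirical p-value with add-one smoothing.

        ``rng`` enables randomized tie-breaking — the standard device that
        makes p-values of a *discrete* statistic exactly uniform under the
        null (used by calibration checks; default is the conservative
        deterministic form).
        """
        v = self.values
        m = v.size
        if tail == "low":
            lt = int(np.searchsorted(v, observed, side="left"))
            le = int(np.searchsorted(v, observed, side="right"))
            if rng is None:
                return float((1 + le) / (m + 1))
            return float((lt + rng.uniform() * (1 + le - lt)) / (m + 1))
        gt = m - int(np.searchsorted(v, observed, side="right"))
        ge = m - int(np.searchsorted(v, observed, side="left"))
        if rng is None:
            return float((1 + ge) / (m + 1))
        return float((gt + rng.uniform() * (1 + ge - gt)) / (m + 1))


@dataclass
class DatingResult:
    time_years: float
    uncertainty: float
    method: str
    mu: float


# ---------------------------------------------------------------------------
# spectrum construction
# ---------------------------------------------------------------------------

def build_phi2d(
    m: HaplotypeMatrix,
    core_site: str,
    core_allele: int,
    region: Region | None = None,
) -> Phi2D:
    """Tally the 2D SFS partitioned by carrier status of the core allele.

    For each segregating non-core site in the region, ``i`` is the derived
    count among D-group haplotypes (carriers of ``core_allele`` at the core
    site) and ``j`` the derived count among the rest.  Monomorphic sites are
    skipped; the core site itself is excluded.
    """
    core_idx = m.site_index(core_site)
    core_col = m.alleles[:, core_idx]
    d_mask = core_col == core_allele
    n_D = int(d_mask.sum())
    n_O = m.n_haplotypes - n_D
    if n_D < 2:
        raise ValueError("core allele must be carried by >= 2 haplotypes")
    sub = m.subset_region(region) if region is not None else m
    phi = np.zeros((n_D + 1, n_O + 1), dtype=np.int64)
    not_core = np.array([sid != core_site for sid in sub.site_ids])
    totals = sub.alleles.sum(axis=0)
    seg = not_core & (totals > 0) & (totals < m.n_haplotypes)
    i_in = sub.alleles[np.ix_(d_mask, seg)].sum(axis=0)
    j_out = totals[seg] - i_in
    np.add.at(phi, (i_in, j_out), 1)
    n_seg = int(seg.sum())
    if region is not None:
        region_bp = region.end - region.start + 1
    elif sub.n_sites:
        region_bp = int(sub.positions[-1] - sub.positions[0] + 1)
    else:
        region_bp = 1
    return Phi2D(
        matrix=phi,
        n_D=n_D,
        n_O=n_O,
        core_site=core_site,
        core_allele=core_allele,
        n_region_sites=n_seg,
        region_bp=region_bp,
    )


def iav_stats(phi: Phi2D, top_k: int = 10) -> IAVSummary:
    """Summary statistics of a 2D spectrum.

    Fallback definitions (documented surrogates for the published forms):

    * ``F_c``   = D-exclusive segregating sites / all segregating sites
    * ``G_c0``  = sum_i i * Phi[i, 0] / n_D (mean exclusive-variant dosage)
    * ``L_c0``  = G_c0 / region span in bp (exclusive dosage per length)
    * ``G*_c0`` = sum_{i, j>0} i * Phi[i, j] / n_D (shared-site analogue)
    * ``gamma*(10)`` = fraction of the ``top_k`` highest-i sites that are
      shared (j > 0)
    * ``i_max``  = max i with Phi[i, 0] > 0;  ``i*_max`` = max i with any
      Phi[i, j>0] > 0

    Low unstarred values signal low intra-allelic variability (sweep-like
    star genealogy in the D group).
    """
    mat = phi.matrix
    i_idx = np.arange(mat.shape[0])
    excl = mat[:, 0]  # D-exclusive sites (j = 0), includes i = 0 row = 0 sites
    excl = excl.copy()
    excl[0] = 0  # i = 0, j = 0 would be monomorphic; defensive
    shared = mat[:, 1:]
    n_excl = int(excl.sum())
    n_all = phi.n_region_sites
    degenerate = n_excl == 0
    f_c = n_excl / n_all if n_all else math.nan
    g_c0 = float((i_idx * excl).sum() / phi.n_D)
    l_c0 = g_c0 / phi.region_bp
    g_star = float((i_idx[:, None] * shared).sum() / phi.n_D)
    i_max = int(i_idx[excl > 0].max()) if (excl > 0).any() else 0
    shared_any = shared.sum(axis=1)
    i_star_max = int(i_idx[shared_any > 0].max()) if (shared_any > 0).any() else 0
    # gamma*(10): among the top_k sites with the highest within-D carrier
    # count i, the fraction that are shared with outsiders.
    sites = []  # (i, is_shared) expanded per site
    for i in i_idx[1:]:
        sites += [(int(i), False)] * int(excl[i])
        sites += [(int(i), True)] * int(shared_any[i])
    sites.sort(key=lambda t: t[0], reverse=True)
    top = sites[:top_k]
    gamma = sum(1 for _, s in top if s) / len(top) if top else math.nan
    return IAVSummary(
        F_c=float(f_c),
        G_c0=g_c0,
        L_c0=float(l_c0),
        G_star_c0=g_star,
        gamma_star_10=float(gamma),
        i_max=i_max,
        i_star_max=i_star_max,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# null distributions and tests
# ---------------------------------------------------------------------------

def iav_null_summaries(
    demography,
    core_freq: float,
    n_reps: int,
    seed: int | None = None,
    freq_tol: float | None = None,
) -> list[IAVSummary]:
    """Neutral-model IAV summaries conditioned on the core frequency.

    Coalescent replicates (via the internal ms-equivalent engine in
    :mod:`popgenkit.synth`) are accepted when they contain a site whose
    derived frequency matches ``core_freq`` within ``freq_tol`` (default
    1/n); that site plays the role of the core.  ``demography`` is a
    :class:`popgenkit.synth.CoalescentConfig`.
    """
    from .synth import CoalescentConfig, simulate_coalescent

    if freq_tol is None:
        freq_tol = 1.0 / demography.n
    out: list[IAVSummary] = []
    rng = np.random.default_rng(seed)
    attempts = 0
    max_attempts = 50 * n_reps
    while len(out) < n_reps and attempts < max_attempts:
        attempts += 1
        cfg = CoalescentConfig(
            n=demography.n,
            theta=demography.theta,
            rho=demography.rho,
            hotspot=demography.hotspot,
            sizes=demography.sizes,
            N0=demography.N0,
            length=demography.length,
            seed=int(rng.integers(1, 2**31 - 1)),
        )
        mat = simulate_coalescent(cfg)
        if mat.n_sites < 2:
            continue
        freqs = mat.derived_freqs()
        match = np.flatnonzero(np.abs(freqs - core_freq) <= freq_tol)
        if match.size == 0:
            continue
        core = mat.site_ids[int(match[rng.integers(match.size)])]
        out.append(iav_stats(build_phi2d(mat, core, 1)))
    if len(out) < n_reps:
        warnings.warn(
            f"only {len(out)}/{n_reps} accepted replicates matched the frequency condition"
        )
    return out


def null_distribution(
    statistic: str,
    demography,
    n: int,
    region_length: float,
    core_freq: float,
    n_reps: int = 1000,
    seed: int | None = None,
    freq_tol: float | None = None,
    allow_few_reps: bool = False,
    summaries: list[IAVSummary] | None = None,
) -> NullDistribution:
    """Neutral null distribution of one IAV statistic.

    Precomputed ``summaries`` (from :func:`iav_null_summaries`) may be
    passed so that one simulation batch serves every statistic.
    """
    from .synth import CoalescentConfig

    if statistic not in IAV_STATS + ("G_star_c0", "gamma_star_10", "i_max", "i_star_max"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_reps < 1000 and not allow_few_reps:
        warnings.warn("fewer than 1000 null replicates; pass allow_few_reps=True to accept")
    if summaries is None:
        if demography is None:
            demography = CoalescentConfig(n=n, theta=region_length, seed=seed)
        summaries = iav_null_summaries(demography, core_freq, n_reps, seed, freq_tol)
    values = np.sort(np.asarray([getattr(s, statistic) for s in summaries], dtype=float))
    return NullDistribution(
        statistic=statistic,
        values=values,
        n_reps=len(values),
        scenario="neutral",
        seed=seed,
    )


def sweep_test(
    summary: IAVSummary,
    nulls: dict[str, NullDistribution],
    q_threshold: float = 0.05,
    min_significant: int = 2,
) -> dict:
    """Empirical one-sided (low-tail) test of the three IAV statistics.

    BH-corrects the p-values across the tested set; the call is positive
    selection when at least ``min_significant`` of F_c, G_c0, L_c0 reach
    ``q < q_threshold``.
    """
    for s in IAV_STATS:
        if s not in nulls:
            raise ValueError(f"missing null distribution for {s}")
    ps = np.array([nulls[s].empirical_p(getattr(summary, s), tail="low") for s in IAV_STATS])
    qs = bh_fdr(ps)
    summary.q_values = dict(zip(IAV_STATS, qs))
    n_sig = int((qs < q_threshold).sum())
    return {
        "p_values": dict(zip(IAV_STATS, ps)),
        "q_values": summary.q_values,
        "n_significant": n_sig,
        "call": "positive_selection" if n_sig >= min_significant else "no_signal",
    }


# ---------------------------------------------------------------------------
# subhaplotypes
# ---------------------------------------------------------------------------

def classify_subhaplotypes(
    m: HaplotypeMatrix,
    core_site: str,
    tag_sites: tuple[str, str],
) -> dict:
    """Partition D-group haplotypes by allele combination at two tag sites.

    Derived at both tags -> ``derived`` class (A-G); ancestral at both ->
    ``ancestral`` class (C-A); mixed -> ``recombinant``.
    """
    core_idx = m.site_index(core_site)
    t1, t2 = (m.site_index(s) for s in tag_sites)
    for t in (t1, t2):
        col = m.alleles[:, t]
        if col.min() == col.max():
            raise ValueError(f"tag site {m.site_ids[t]!r} is monomorphic")
    d_idx = np.flatnonzero(m.alleles[:, core_idx] == 1)
    labels = {}
    classes = {"A-G": [], "C-A": [], "recombinant": []}
    for h in d_idx:
        a, b = m.alleles[h, t1], m.alleles[h, t2]
        if a == 1 and b == 1:
            lab = "A-G"
        elif a == 0 and b == 0:
            lab = "C-A"
        else:
            lab = "recombinant"
        labels[int(h)] = lab
        classes[lab].append(int(h))
    return {
        "labels": labels,
        "classes": classes,
        "counts": {k: len(v) for k, v in classes.items()},
        "tag_sites": tuple(tag_sites),
        "n_D": d_idx.size,
    }


def remove_recombinants(
    m: HaplotypeMatrix,
    core_site: str,
    diag_diff: float = 0.8,
    vote_threshold: float = 0.9,
) -> tuple[HaplotypeMatrix, list[int]]:
    """Drop haplotypes that mix the two core-class diagnostic patterns.

    Diagnostic sites are those whose derived frequency differs between the
    derived-core and ancestral-core classes by more than ``diag_diff``.  A
    haplotype whose majority vote over diagnostic sites agrees with its own
    class majority in fewer than ``vote_threshold`` of sites is flagged as
    a recombinant mosaic and removed.  If every haplotype would be removed,
    a warning is issued and nothing is removed (degenerate guard).  This
    detector is a documented surrogate; no published rule is specified.
    """
    core_idx = m.site_index(core_site)
    core_col = m.alleles[:, core_idx]
    d_mask = core_col == 1
    if d_mask.all() or not d_mask.any():
        return m, []
    f_d = m.alleles[d_mask].mean(axis=0)
    f_o = m.alleles[~d_mask].mean(axis=0)
    diag = np.flatnonzero(np.abs(f_d - f_o) > diag_diff)
    diag = diag[diag != core_idx]
    if diag.size == 0:
        return m, []
    # class-majority allele at each diagnostic site
    maj_d = (f_d[diag] > 0.5).astype(np.int8)
    maj_o = (f_o[diag] > 0.5).astype(np.int8)
    removed = []
    for h in range(m.n_haplotypes):
        own = maj_d if d_mask[h] else maj_o
        agree = (m.alleles[h, diag] == own).mean()
        if agree < vote_threshold:
            removed.append(h)
    rm = np.asarray(removed, dtype=int)
    if rm.size and (d_mask[rm].sum() == d_mask.sum() or (~d_mask)[rm].sum() == (~d_mask).sum()):
        warnings.warn("an entire core class looks mosaic; refusing to remove any haplotype")
        return m, []
    keep = np.setdiff1d(np.arange(m.n_haplotypes), removed)
    return m.take_haplotypes(keep), removed


# ---------------------------------------------------------------------------
# dating
# ---------------------------------------------------------------------------

def divergence_time(pi_between: float, mu: float) -> DatingResult:
    """Divergence time T = pi_between / (2 mu) in years."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if pi_between < 0:
        raise ValueError("diversity must be non-negative")
    return DatingResult(
        time_years=pi_between / (2.0 * mu),
        uncertainty=0.0,
        method="pairwise-divergence",
        mu=mu,
    )


def tmrca_within(
    group: HaplotypeMatrix,
    mu: float,
    method: str = "pairwise-divergence",
) -> DatingResult:
    """TMRCA of a haplotype group from within-group diversity.

    ``pairwise-divergence``: pi_within/(2 mu).  ``mean-derived-count``
    (Thomson-style): mean per-haplotype count of derived alleles at sites
    segregating within the group, divided by mu * L.  The spread is 1.96 x
    the standard error of the underlying per-haplotype/per-pair quantity.
    """
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if group.n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes in the group")
    L = group.n_sites
    if method == "pairwise-divergence":
        div = nucleotide_diversity(group)
        t = div.pi / (2.0 * mu)
        # spread from the across-pair variance of per-site differences
        h = group.alleles
        n = h.shape[0]
        diffs = [
            (h[i] != h[j]).sum() / L for i in range(n) for j in range(i + 1, n)
        ]
        se = float(np.std(diffs, ddof=1) / math.sqrt(len(diffs))) if len(diffs) > 1 else 0.0
        return DatingResult(t, 1.96 * se / (2.0 * mu), "pairwise-divergence", mu)
    if method == "mean-derived-count":
        counts = group.derived_counts()
        seg = (counts > 0) & (counts < group.n_haplotypes)
        per_hap = group.alleles[:, seg].sum(axis=1).astype(float)
        mean_k = float(per_hap.mean())
        t = mean_k / (mu * L)
        se = float(per_hap.std(ddof=1) / math.sqrt(per_hap.size)) if per_hap.size > 1 else 0.0
        return DatingResult(t, 1.96 * se / (mu * L), "mean-derived-count", mu)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# sweep mode
# ---------------------------------------------------------------------------

def sweep_mode(d_group_call: str, subhap_calls: dict[str, str]) -> str:
    """Decision table combining whole-D and per-subhaplotype test calls.

    * D group significant and exactly one selected subhaplotype -> hard
    * D group significant and >= 2 selected subhaplotypes -> soft
    * D group not significant but exactly one subhaplotype is -> hardening
    * otherwise -> none
    """
    if not subhap_calls:
        raise ValueError("missing subhaplotype test results")
    n_sel = sum(1 for c in subhap_calls.values() if c == "positive_selection")
    d_sig = d_group_call == "positive_selection"
    if d_sig and n_sel >= 2:
        return "soft"
    if d_sig and n_sel == 1:
        return "hard"
    if d_sig and n_sel == 0:
        return "hard"  # single undifferentiated selected lineage
    if not d_sig and n_sel == 1:
        return "hardening"
    return "none"
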