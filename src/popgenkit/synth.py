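"""Synthetic-data generators.

Everything the analysis stages need can be produced offline: neutral
coalescent haplotype panels (ms-equivalent, backed by msprime), sweep /
subhaplotype fixtures with known truth labels, two-population FST-tuned
panels, a right-skewed surrogate for a genome-wide FST distribution,
ancient-record fixtures, and VCF round-trip serialization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import msprime
import numpy as np

from .types import HaplotypeMatrix

__all__ = [
    "CoalescentConfig",
    "SweepFixtureConfig",
    "simulate_coalescent",
    "make_sweep_fixture",
    "sweep_fixture_ladder",
    "make_two_pop_panel",
    "surrogate_empirical_fst",
    "write_vcf",
    "read_vcf",
    "export_ms",
]


# ---------------------------------------------------------------------------
# coalescent engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoalescentConfig:
    """Neutral coalescent with recombination, ms-style region scaling.

    ``theta`` and ``rho`` are scaled to the whole region (theta = 2 N mu L
    for haploid samples).  ``hotspot`` is ``(start_frac, end_frac,
    fold_increase)`` of the recombination rate.  ``sizes`` is a tuple of
    ``(time_generations, size)`` piecewise-constant changes backward in
    time; the present-day size is ``N0``.
    """

    n: int
    theta: float
    rho: float = 0.0
    hotspot: tuple | None = None
    sizes: tuple = ()
    N0: int = 10_000
    length: float = 20_000.0
    start_bp: int = 1
    chrom: str = "1"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.theta < 0 or self.rho < 0:
            raise ValueError("theta and rho must be non-negative")
        if self.n < 2:
            raise ValueError("need >= 2 samples")


def simulate_coalescent(cfg: CoalescentConfig) -> HaplotypeMatrix:
    """Standard neutral coalescent with infinite-sites mutations.

    Ancestral states are 0 by construction; positions are mapped onto
    strictly increasing integer coordinates within the region.
    """
    seed = cfg.seed if cfg.seed is not None else 1
    demography = msprime.Demography()
    demography.add_population(name="pop0", initial_size=cfg.N0)
    for t, size in cfg.sizes:
        demography.add_population_parameters_change(time=t, initial_size=size)
    rec_rate = cfg.rho / (2.0 * cfg.N0 * cfg.length)
    if cfg.hotspot is not None and cfg.rho > 0:
        lo, hi, fold = cfg.hotspot
        rate_map = msprime.RateMap(
            position=[0.0, lo * cfg.length, hi * cfg.length, cfg.length],
            rate=[rec_rate, rec_rate * fold, rec_rate],
        )
    else:
        rate_map = rec_rate
    ts = msprime.sim_ancestry(
        samples=cfg.n,
        ploidy=1,
        demography=demography,
        sequence_length=cfg.length,
        recombination_rate=rate_map,
        discrete_genome=False,
        random_seed=seed,
    )
    mu = cfg.theta / (2.0 * cfg.N0 * cfg.length)
    ts = msprime.sim_mutations(
        ts,
        rate=mu,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=seed + 1,
    )
    gm = ts.genotype_matrix()  # sites x samples
    if gm.size == 0:
        return HaplotypeMatrix(
            np.zeros((cfg.n, 0), dtype=np.int8), [], [], None, cfg.chrom
        )
    alleles = (gm.T > 0).astype(np.int8)
    positions = []
    prev = cfg.start_bp - 1
    for p in ts.sites_position:
        pos = max(prev + 1, cfg.start_bp + int(p))
        positions.append(pos)
        prev = pos
    return HaplotypeMatrix(alleles, positions, chrom=cfg.chrom)


def export_ms(matrices: list[HaplotypeMatrix], path: str, command: str = "popgenkit") -> None:
    """Write replicates in ms text format for cross-validation."""
    with open(path, "w") as fh:
        fh.write(f"{command}\n0 0 0\n")
        for m in matrices:
            fh.write("\n//\n")
            fh.write(f"segsites: {m.n_sites}\n")
            span = max(float(m.positions[-1]) if m.n_sites else 1.0, 1.0)
            pos = " ".join(f"{p / span:.5f}" for p in m.positions)
            fh.write(f"positions: {pos}\n")
            for row in m.alleles:
                fh.write("".join(str(int(x)) for x in row) + "\n")


# ---------------------------------------------------------------------------
# sweep / subhaplotype fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepFixtureConfig:
    """Phased haplotype block with a core site splitting the sample into a
    derived (sweep-candidate) class and an ancestral class.

    The derived class is built from one or two recent star-like clades over
    a shared older background.  ``diversity_scalars`` set the expected
    number of private mutations per clade haplotype (0 = perfect star tips,
    i.e. zero intra-clade diversity).  ``shared_old_variants`` sites are
    carried by a whole clade plus some ancestral-class haplotypes (these
    drive i*_max).  Sites beyond ``ld_break_frac`` of the region have their
    rows independently permuted, emulating a flanking recombination hotspot
    that destroys LD with the core.
    """

    n_total: int = 206
    n_derived: int = 155
    split: tuple = (75, 80)
    diversity_scalars: tuple = (0.5, 0.5)
    internal_sites: tuple = (0, 0)  # clade-internal (i in 2..c-1) site counts
    shared_old_variants: int = 6
    n_background_sites: int = 60
    region_bp: int = 22_000
    start_bp: int = 100_000
    ld_break_frac: float = 0.75
    neutral: bool = False  # draw the whole panel from a neutral coalescent
    theta: float = 30.0  # coalescent theta used in neutral mode
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.split) != self.n_derived:
            raise ValueError("subhaplotype split must sum to the derived-class size")
        if self.n_derived >= self.n_total:
            raise ValueError("derived class must leave >= 1 ancestral haplotype")
        if any(s < 0 for s in self.diversity_scalars):
            raise ValueError("diversity scalars must be >= 0")


def make_sweep_fixture(cfg: SweepFixtureConfig) -> tuple[HaplotypeMatrix, dict]:
    """Build the fixture and its truth labels.

    Row layout: the first ``split[0]`` haplotypes are the derived-tag clade
    ("A-G"), the next ``split[1]`` the ancestral-tag clade ("C-A"), the
    remainder the ancestral core class ("T").  The two tag sites are derived
    exactly on the A-G clade, so subhaplotype classification can recover the
    split with no recombinants.
    """
    if cfg.neutral:
        return _make_neutral_fixture(cfg)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_total
    a, b = cfg.split
    d = cfg.n_derived
    t_idx = np.arange(d, n)
    clade_rows = [np.arange(0, a), np.arange(a, a + b)]

    cols: list[np.ndarray] = []  # allele columns
    ids: list[str] = []
    in_core: list[bool] = []  # whether the site sits inside the tight LD core

    def add(col: np.ndarray, sid: str, core: bool) -> None:
        cols.append(col.astype(np.int8))
        ids.append(sid)
        in_core.append(core)

    core_col = np.zeros(n, dtype=np.int8)
    core_col[:d] = 1
    add(core_col, "core", True)

    for k in (1, 2):
        tag = np.zeros(n, dtype=np.int8)
        tag[clade_rows[0]] = 1
        add(tag, f"tag{k}", True)

    # shared old variants: whole clade + a non-empty ancestral-class subset
    for k in range(cfg.shared_old_variants):
        clade = clade_rows[k % 2]
        col = np.zeros(n, dtype=np.int8)
        col[clade] = 1
        n_out = int(rng.integers(1, max(2, t_idx.size // 3)))
        col[rng.choice(t_idx, size=n_out, replace=False)] = 1
        add(col, f"shared{k}", True)

    # clade-private singletons (intra-allelic variability knob)
    sing = 0
    for clade, scal in zip(clade_rows, cfg.diversity_scalars):
        for h in clade:
            for _ in range(rng.poisson(scal)):
                col = np.zeros(n, dtype=np.int8)
                col[h] = 1
                add(col, f"priv{sing}", True)
                sing += 1
    # optional clade-internal shared mutations
    for clade, n_int in zip(clade_rows, cfg.internal_sites):
        for k in range(n_int):
            size = int(rng.integers(2, max(3, clade.size)))
            col = np.zeros(n, dtype=np.int8)
            col[rng.choice(clade, size=size, replace=False)] = 1
            add(col, f"int{clade[0]}_{k}", True)

    # ancestral-class background diversity, half inside / half outside core
    for k in range(cfg.n_background_sites):
        col = np.zeros(n, dtype=np.int8)
        m_car = int(rng.integers(1, max(2, t_idx.size)))
        col[rng.choice(t_idx, size=m_car, replace=False)] = 1
        add(col, f"bg{k}", k % 2 == 0)

    cols_arr = np.column_stack(cols)
    n_sites = cols_arr.shape[1]
    # positions: core sites inside the central ld_break window, others outside
    half = cfg.region_bp // 2
    core_lo = cfg.start_bp + int(half * (1 - cfg.ld_break_frac))
    core_hi = cfg.start_bp + int(half * (1 + cfg.ld_break_frac))
    in_core_arr = np.asarray(in_core)
    pos = np.empty(n_sites, dtype=np.int64)
    n_in = int(in_core_arr.sum())
    pos[in_core_arr] = np.sort(
        rng.choice(np.arange(core_lo, core_hi), size=n_in, replace=False)
    )
    out_space = np.concatenate(
        [
            np.arange(cfg.start_bp, core_lo),
            np.arange(core_hi + 1, cfg.start_bp + cfg.region_bp),
        ]
    )
    pos[~in_core_arr] = np.sort(
        rng.choice(out_space, size=n_sites - n_in, replace=False)
    )
    # outside the LD core the hotspot has shuffled haplotype backgrounds
    for j in np.flatnonzero(~in_core_arr):
        cols_arr[:, j] = rng.permutation(cols_arr[:, j])
    order = np.argsort(pos)
    matrix = HaplotypeMatrix(
        cols_arr[:, order],
        pos[order],
        [ids[i] for i in order],
        ["pop0"] * n,
        chrom="8",
    )
    truth = {
        "class": ["A-G"] * a + ["C-A"] * b + ["T"] * (n - d),
        "core_site": "core",
        "tag_sites": ("tag1", "tag2"),
        "split": (a, b),
        "core_region": (int(matrix.positions[0]), core_lo, core_hi),
    }
    return matrix, truth


def _make_neutral_fixture(cfg: SweepFixtureConfig) -> tuple[HaplotypeMatrix, dict]:
    """No-sweep fixture: a plain neutral coalescent panel whose core is the
    segregating site closest to the requested derived-class frequency."""
    target = cfg.n_derived / cfg.n_total
    rng = np.random.default_rng(cfg.seed)
    for _ in range(200):
        m = simulate_coalescent(
            CoalescentConfig(
                n=cfg.n_total,
                theta=cfg.theta,
                length=float(cfg.region_bp),
                start_bp=cfg.start_bp,
                chrom="8",
                seed=int(rng.integers(1, 2**31 - 1)),
            )
        )
        if m.n_sites < 3:
            continue
        freqs = m.derived_freqs()
        j = int(np.argmin(np.abs(freqs - target)))
        if abs(freqs[j] - target) <= 2.0 / cfg.n_total:
            break
    ids = list(m.site_ids)
    ids[j] = "core"
    m = HaplotypeMatrix(m.alleles, m.positions, ids, m.pop_labels, m.chrom)
    classes = np.where(m.alleles[:, j] == 1, "D", "T")
    truth = {
        "class": classes.tolist(),
        "core_site": "core",
        "tag_sites": None,
        "split": None,
        "core_region": None,
        "neutral": True,
    }
    return m, truth


def sweep_fixture_ladder(
    cfg: SweepFixtureConfig, scalars: list[float], seed: int = 0
) -> list[tuple[HaplotypeMatrix, dict]]:
    """Fixtures of decreasing intra-allelic diversity sharing one mutation
    layout: the strongest-diversity fixture is generated once and weaker
    rungs are produced by thinning its D-private sites, so the D-exclusive
    site set is nested along the ladder."""
    top = max(scalars)
    base_cfg = SweepFixtureConfig(
        **{**cfg.__dict__, "diversity_scalars": (top, top), "seed": seed}
    )
    base, truth = make_sweep_fixture(base_cfg)
    rng = np.random.default_rng(seed + 1)
    priv = [i for i, s in enumerate(base.site_ids) if s.startswith(("priv", "int"))]
    order = rng.permutation(priv)
    out = []
    for sc in sorted(scalars, reverse=True):
        keep_n = int(round(len(priv) * (sc / top))) if top > 0 else 0
        drop = set(order[keep_n:].tolist())
        idx = [i for i in range(base.n_sites) if i not in drop]
        out.append((base.take_sites(idx), truth))
    return out


# ---------------------------------------------------------------------------
# two-population panel and surrogate FST distribution
# ---------------------------------------------------------------------------

def make_two_pop_panel(
    target_fst: float,
    n1: int,
    n2: int,
    seed: int = 0,
    n_sites: int = 101,
    pops: tuple = ("pop1", "pop2"),
) -> tuple[HaplotypeMatrix, HaplotypeMatrix]:
    """Island-model two-population panel with a core site tuned so its
    realized Hudson FST lands within ~0.05 of ``target_fst``.

    Population frequencies follow the Balding-Nichols beta model with
    differentiation parameter F = ``target_fst``.  The shared site list
    makes the pair directly usable by ``fst_scan``.
    """
    if not 0.0 <= target_fst <= 0.9:
        raise ValueError("target_fst must be in [0, 0.9]")
    rng = np.random.default_rng(seed)
    F = target_fst

    def pop_freqs(p: float) -> tuple[float, float]:
        if F == 0.0:
            return p, p
        shape = (1 - F) / F
        return (
            float(rng.beta(p * shape, (1 - p) * shape)),
            float(rng.beta(p * shape, (1 - p) * shape)),
        )

    def draw_col(p: float, nh: int) -> np.ndarray:
        return (rng.random(nh) < p).astype(np.int8)

    core = n_sites // 2
    a1 = np.zeros((n1, n_sites), dtype=np.int8)
    a2 = np.zeros((n2, n_sites), dtype=np.int8)
    for j in range(n_sites):
        if j == core:
            continue
        p = float(rng.uniform(0.05, 0.95))
        q1, q2 = pop_freqs(p)
        a1[:, j] = draw_col(q1, n1)
        a2[:, j] = draw_col(q2, n2)
    # tune the core column
    best = None
    for _ in range(400):
        q1, q2 = pop_freqs(0.5)
        c1, c2 = draw_col(q1, n1), draw_col(q2, n2)
        p1, p2 = c1.mean(), c2.mean()
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        if den == 0:
            continue
        err = abs(num / den - target_fst)
        if best is None or err < best[0]:
            best = (err, c1, c2)
        if err <= 0.02:
            break
    a1[:, core], a2[:, core] = best[1], best[2]
    positions = np.arange(1, n_sites + 1) * 100
    ids = [f"s{j}" for j in range(n_sites)]
    ids[core] = "core"
    m1 = HaplotypeMatrix(a1, positions, ids, [pops[0]] * n1, chrom="1")
    m2 = HaplotypeMatrix(a2, positions, ids, [pops[1]] * n2, chrom="1")
    return m1, m2


def surrogate_empirical_fst(
    n_snps: int,
    mean: float = 4.8e-3,
    shape: float = 0.35,
    seed: int = 0,
) -> np.ndarray:
    """Right-skewed surrogate for a genome-wide FST distribution (gamma
    with the requested mean)."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.gamma(shape, mean / shape, size=n_snps)


# ---------------------------------------------------------------------------
# VCF round trip
# ---------------------------------------------------------------------------

def write_vcf(m: HaplotypeMatrix, path: str, sample_prefix: str = "S") -> None:
    """Serialize a haplotype matrix as a phased VCF 4.2 with INFO/AA.

    Consecutive haplotype pairs form diploid samples, so the haplotype
    count must be even.  Ancestral alleles are written as REF.
    """
    if m.n_haplotypes % 2 != 0:
        raise ValueError("need an even number of haplotypes to form diploid samples")
    n_samples = m.n_haplotypes // 2
    names = [f"{sample_prefix}{i}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={m.chrom}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n")
        for j in range(m.n_sites):
            gts = "\t".join(
                f"{m.alleles[2 * i, j]}|{m.alleles[2 * i + 1, j]}" for i in range(n_samples)
            )
            fh.write(
                f"{m.chrom}\t{m.positions[j]}\t{m.site_ids[j]}\tA\tG\t.\tPASS\tAA=A\tGT\t{gts}\n"
            )


def write_panel(m: HaplotypeMatrix, path: str, sample_prefix: str = "S") -> None:
    """Population panel TSV (sample_id, pop) matching :func:`write_vcf`."""
    with open(path, "w") as fh:
        fh.write("sample_id\tpop\n")
        for i in range(m.n_haplotypes // 2):
            fh.write(f"{sample_prefix}{i}\t{m.pop_labels[2 * i]}\n")


def read_vcf(path: str, panel: dict[str, str] | None = None) -> HaplotypeMatrix:
    """Ingest a phased VCF into a polarized haplotype matrix.

    Multiallelic records, sites lacking a usable INFO/AA annotation and
    sites with missing genotypes are dropped (with a warning for missing
    polarity).  When AA equals ALT the site is flipped so 1 is always the
    derived allele.  ``panel`` maps sample id -> population label.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    cols, positions, ids = [], [], []
    chrom = "1"
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        aa = var.INFO.get("AA")
        if aa is None:
            warnings.warn(f"site {var.ID or var.POS} lacks AA annotation; dropped")
            continue
        aa = str(aa).upper()
        if aa not in (var.REF.upper(), var.ALT[0].upper()):
            warnings.warn(f"site {var.ID or var.POS} AA matches neither allele; dropped")
            continue
        gts = np.asarray([g[:2] for g in var.genotypes], dtype=int)
        if (gts < 0).any():
            continue
        col = gts.reshape(-1)
        if aa == var.ALT[0].upper():
            col = 1 - col
        chrom = var.CHROM
        cols.append(col.astype(np.int8))
        positions.append(var.POS)
        ids.append(var.ID if var.ID not in (None, ".") else f"site{var.POS}")
    if not cols:
        return HaplotypeMatrix(np.zeros((2 * len(samples), 0), dtype=np.int8), [], [], None, chrom)
    alleles = np.column_stack(cols)
    labels = []
    for s in samples:
        lab = (panel or {}).get(s, "pop0")
        labels += [lab, lab]
    return HaplotypeMatrix(alleles, positions, ids, labels, chrom)
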