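"""Haplotype census across populations and post-call ancient-DNA site filters.

The filter policies reproduce per-sample quality rules for three ancient
genomes: a low-coverage consensus-haploid sample (IK002-style), a
high-coverage diploid sample (FUN23-style), and a low-coverage haploid
sample (FUN5-style).  Upstream variant calling is out of scope; its outputs
are modeled as :class:`AncientSiteRecord` fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import HaplotypeMatrix

__all__ = [
    "AncientSiteRecord",
    "FilterPolicy",
    "POLICIES",
    "haplotype_census",
    "filter_ancient_sites",
    "consensus_haploidize",
    "remove_ancient_singletons",
]


@dataclass(frozen=True)
class AncientSiteRecord:
    position: int
    alleles: tuple  # (ref-ish allele, alt-ish allele)
    depth: int
    allele_depths: tuple
    genotype_quality: float
    mapping_quality: float
    base_quality: float
    in_1kgp: bool = True

    def __post_init__(self) -> None:
        if self.depth < sum(self.allele_depths):
            raise ValueError("total depth below the sum of allele depths")
        for q in (self.genotype_quality, self.mapping_quality, self.base_quality):
            if q < 0:
                raise ValueError("qualities must be non-negative")


@dataclass(frozen=True)
class FilterPolicy:
    sample: str
    min_mq: float | None = None  # reject when MQ < min_mq
    min_bq: float | None = None
    min_depth: int | None = None  # keep when depth > min_depth
    min_gq: float | None = None  # keep when GQ > min_gq
    ploidy: str = "consensus-haploid"  # or "diploid"
    require_1kgp: bool = True


POLICIES = {
    "IK002": FilterPolicy("IK002", min_mq=20, min_bq=10, min_depth=2, min_gq=1,
                          ploidy="consensus-haploid"),
    "FUN23": FilterPolicy("FUN23", min_gq=30, min_depth=30, ploidy="diploid"),
    "FUN5": FilterPolicy("FUN5", min_gq=20, ploidy="consensus-haploid"),
}


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------

def haplotype_census(m: HaplotypeMatrix, core_site: str) -> pd.DataFrame:
    """Collapse identical haplotype sequences and tag each distinct
    haplotype by its populations of occurrence and its core allele.

    Returns one row per distinct haplotype with per-population counts, a
    ``shared`` flag (seen in more than one population) and the core-allele
    class.  Summary fractions (e.g. share of population-specific haplotypes
    carrying the derived core allele) live in ``DataFrame.attrs``.
    """
    pops = sorted(set(m.pop_labels))
    if len(pops) < 2:
        raise ValueError("census needs >= 2 labeled populations")
    core_idx = m.site_index(core_site)
    seqs, inverse = np.unique(m.alleles, axis=0, return_inverse=True)
    rows = []
    for k in range(seqs.shape[0]):
        members = np.flatnonzero(inverse == k)
        counts = {p: int((m.pop_labels[members] == p).sum()) for p in pops}
        present = [p for p in pops if counts[p] > 0]
        rows.append(
            {
                "haplotype": k,
                "core_allele": int(seqs[k, core_idx]),
                **{f"n_{p}": counts[p] for p in pops},
                "total": int(members.size),
                "shared": len(present) > 1,
                "specific_to": present[0] if len(present) == 1 else "",
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_distinct"] = len(df)
    df.attrs["n_shared"] = int(df["shared"].sum())
    for p in pops:
        spec = df[df["specific_to"] == p]
        df.attrs[f"n_specific_{p}"] = len(spec)
        df.attrs[f"frac_derived_core_specific_{p}"] = (
            float((spec["core_allele"] == 1).mean()) if len(spec) else float("nan")
        )
    return df


# ---------------------------------------------------------------------------
# site filtering
# ---------------------------------------------------------------------------

def filter_ancient_sites(
    records: list[AncientSiteRecord],
    policy: FilterPolicy | str,
) -> tuple[list[AncientSiteRecord], dict[int, str]]:
    """Apply a per-sample quality policy; returns kept records and a
    position -> rejection-reason map for the dropped ones."""
    if isinstance(policy, str):
        try:
            policy = POLICIES[policy]
        except KeyError as exc:
            raise ValueError(f"unknown policy tag {policy!r}") from exc
    kept: list[AncientSiteRecord] = []
    rejected: dict[int, str] = {}
    for rec in records:
        reason = _reject_reason(rec, policy)
        if reason is None:
            kept.append(rec)
        else:
            rejected[rec.position] = reason
    return kept, rejected


def _reject_reason(rec: AncientSiteRecord, policy: FilterPolicy) -> str | None:
    if policy.require_1kgp and not rec.in_1kgp:
        return "not-in-1kgp-panel"
    if policy.min_mq is not None and rec.mapping_quality < policy.min_mq:
        return "mapping-quality"
    if policy.min_bq is not None and rec.base_quality < policy.min_bq:
        return "base-quality"
    if policy.min_depth is not None and not rec.depth > policy.min_depth:
        return "depth"
    if policy.min_gq is not None and not rec.genotype_quality > policy.min_gq:
        return "genotype-quality"
    return None


def consensus_haploidize(record: AncientSiteRecord) -> str | None:
    """Single-allele consensus call: the allele with the deeper coverage.

    Equal depths (or zero total depth) yield ``None`` — the site is marked
    missing so that outputs stay deterministic.
    """
    d0, d1 = record.allele_depths
    if d0 + d1 == 0 or d0 == d1:
        return None
    return record.alleles[0] if d0 > d1 else record.alleles[1]


def remove_ancient_singletons(
    ancient_calls: dict[str, dict[int, int]],
    panel: HaplotypeMatrix,
) -> tuple[dict[str, dict[int, int]], list[int]]:
    """Drop sites whose derived allele is unique to one ancient sample.

    ``ancient_calls`` maps sample -> {position: allele (0 ancestral /
    1 derived)}.  A site is removed from every ancient sequence when its
    derived allele is carried by exactly one ancient sample and by no panel
    haplotype (infinite-sites reasoning: such a call cannot be validated).
    """
    pos_to_col = {int(p): i for i, p in enumerate(panel.positions)}
    removed: list[int] = []
    all_positions = sorted({p for calls in ancient_calls.values() for p in calls})
    for pos in all_positions:
        carriers = [s for s, calls in ancient_calls.items() if calls.get(pos) == 1]
        if len(carriers) != 1:
            continue
        col = pos_to_col.get(pos)
        panel_derived = int(panel.alleles[:, col].sum()) if col is not None else 0
        if panel_derived == 0:
            removed.append(pos)
    cleaned = {
        s: {p: a for p, a in calls.items() if p not in removed}
        for s, calls in ancient_calls.items()
    }
    return cleaned, removed
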