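"""Paired rDNA/rRNA activity profiles.

For each sample, relative abundances are computed separately within the
mapped rDNA pool (total community) and the mapped rRNA pool (active
community); their quotient, the rRNA/rDNA ratio, is the per-unit proxy for
cell-level ribosomal amplification. Units present only in the rRNA pool are
"phantom taxa" (no defined ratio); units present only in the rDNA pool are
dormant/dead candidates and carry ratio 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .units import CountTable

PRESENCE_CLASSES = ("shared", "phantom", "dna_only")


@dataclass
class PairedActivityProfile:
    """Per-unit paired-pool profile of one sample.

    ``table`` is indexed by unit_id with columns rdna_count, rrna_count,
    rel_rdna, rel_rrna, ratio, presence_class. Ratios are NaN for phantom
    units and 0 for dna_only units.
    """

    sample: str
    method: str
    table: pd.DataFrame

    def units_in_class(self, presence_class: str) -> pd.DataFrame:
        return self.table[self.table["presence_class"] == presence_class]

    @property
    def shared(self) -> pd.DataFrame:
        return self.units_in_class("shared")


def build_paired_profile(
    count_table: CountTable, sample: str, pseudo_count: int = 0
) -> PairedActivityProfile:
    """Build one sample's paired profile from a mapped count table.

    Relative abundances are fractions of the sample's *mapped* reads per
    pool; units with zero counts in both pools are omitted. ``pseudo_count``
    optionally adds reads to both pools of every detected unit (sensitivity
    mode that gives phantoms a finite ratio); the default of 0 keeps phantom
    ratios undefined.
    """
    counts = count_table.counts
    for pool in ("rDNA", "rRNA"):
        if (sample, pool) not in counts.columns:
            raise KeyError(f"sample {sample!r} lacks a mapped {pool} pool")
    rdna = counts[(sample, "rDNA")].astype(int)
    rrna = counts[(sample, "rRNA")].astype(int)
    if rdna.sum() == 0 or rrna.sum() == 0:
        raise ValueError(f"sample {sample!r} has a pool with zero mapped reads")
    detected = (rdna > 0) | (rrna > 0)
    rdna, rrna = rdna[detected], rrna[detected]
    if pseudo_count:
        rdna = rdna + pseudo_count
        rrna = rrna + pseudo_count
    rel_rdna = rdna / rdna.sum()
    rel_rrna = rrna / rrna.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rdna > 0, rel_rrna / rel_rdna.replace(0, np.nan), np.nan)
    presence = np.where(
        (rdna > 0) & (rrna > 0), "shared",
        np.where(rdna == 0, "phantom", "dna_only"),
    )
    table = pd.DataFrame(
        {"rdna_count": rdna, "rrna_count": rrna,
         "rel_rdna": rel_rdna, "rel_rrna": rel_rrna,
         "ratio": ratio, "presence_class": presence},
        index=rdna.index,
    )
    table.loc[table["presence_class"] == "dna_only", "ratio"] = 0.0
    return PairedActivityProfile(sample, count_table.method, table)


def build_all_profiles(count_table: CountTable,
                       exclude_samples: Sequence[str] = ()) -> list[PairedActivityProfile]:
    """Profiles for every sample in the table that carries both pools."""
    samples = sorted({s for s, _ in count_table.counts.columns})
    out = []
    for sample in samples:
        if sample in exclude_samples:
            continue
        cols = {p for s, p in count_table.counts.columns if s == sample}
        if {"rDNA", "rRNA"} <= cols:
            out.append(build_paired_profile(count_table, sample))
    return out


# ---------------------------------------------------------------------------
# overlap / phantom summaries


@dataclass
class OverlapSummary:
    """Presence-class composition of one sample's detected units."""

    sample: str
    n_shared: int
    n_phantom: int
    n_dna_only: int
    read_fraction: pd.DataFrame  # classes x pools

    @property
    def n_detected(self) -> int:
        return self.n_shared + self.n_phantom + self.n_dna_only

    @property
    def phantom_unit_fraction(self) -> float:
        return self.n_phantom / self.n_detected if self.n_detected else np.nan

    @property
    def phantom_read_fraction(self) -> float:
        return float(self.read_fraction.loc["phantom", "rRNA"])


def overlap_summary(profile: PairedActivityProfile) -> OverlapSummary:
    """Unit counts and read fractions per presence class."""
    t = profile.table
    frac = pd.DataFrame(0.0, index=list(PRESENCE_CLASSES), columns=["rDNA", "rRNA"])
    for cls in PRESENCE_CLASSES:
        rows = t[t["presence_class"] == cls]
        frac.loc[cls, "rDNA"] = rows["rel_rdna"].sum()
        frac.loc[cls, "rRNA"] = rows["rel_rrna"].sum()
    n = t["presence_class"].value_counts()
    return OverlapSummary(
        profile.sample,
        int(n.get("shared", 0)), int(n.get("phantom", 0)), int(n.get("dna_only", 0)),
        frac,
    )


def aggregate_phantom_fraction(profiles: Iterable[PairedActivityProfile]) -> float:
    """Phantom share of all (unit, sample) detections, pooled across samples.

    This is the cross-sample aggregate on which unit-formation methods are
    compared (single-nucleotide units typically produce a larger phantom share
    than 97% clusters on the same noisy reads).
    """
    n_phantom = n_detected = 0
    for p in profiles:
        s = overlap_summary(p)
        n_phantom += s.n_phantom
        n_detected += s.n_detected
    return n_phantom / n_detected if n_detected else np.nan


# ---------------------------------------------------------------------------
# production, correlation, rare-but-active


def relative_production(
    profile: PairedActivityProfile, top_k: int = 10
) -> tuple[pd.DataFrame, float]:
    """Per-unit production and the cumulative curve by abundance rank.

    Production is the unit's fraction of the sample's rRNA pool. Units are
    ordered by decreasing rDNA relative abundance (phantoms, with zero rDNA,
    rank last); the cumulative sum conserves mass, ending at 1. Returns the
    ordered frame (columns rel_rdna, production, cumulative) and the fraction
    of production contributed by the ``top_k`` most abundant units.
    """
    t = profile.table
    # decreasing abundance; exact ties broken by unit id for reproducibility
    t = t.iloc[np.lexsort((t.index.to_numpy(), -t["rel_rdna"].to_numpy()))]
    out = pd.DataFrame(
        {"rel_rdna": t["rel_rdna"], "production": t["rel_rrna"]},
        index=t.index,
    )
    out["cumulative"] = out["production"].cumsum()
    k = min(top_k, len(out))
    top_fraction = float(out["cumulative"].iloc[k - 1]) if k else np.nan
    return out, top_fraction


def log_log_correlation(
    profile: PairedActivityProfile, min_shared: int = 3
) -> tuple[float, float]:
    """Pearson correlation of log10 rRNA vs log10 rDNA relative abundance.

    Restricted to shared units (both pools positive, so logs are finite).
    Returns (rho, two-sided p-value).
    """
    shared = profile.shared
    if len(shared) < min_shared:
        raise ValueError(
            f"need >= {min_shared} shared units, found {len(shared)}")
    r, p = stats.pearsonr(np.log10(shared["rel_rdna"]), np.log10(shared["rel_rrna"]))
    return float(r), float(p)


@dataclass
class RareActiveSummary:
    """Quadrant counts at abundance/ratio thresholds over shared units."""

    abundance_threshold: float
    ratio_threshold: float
    n_rare_active: int      # abundance < threshold, ratio > threshold
    n_abundant_active: int
    n_rare_quiet: int
    n_abundant_quiet: int

    @property
    def fraction_active_that_are_rare(self) -> float:
        active = self.n_rare_active + self.n_abundant_active
        return self.n_rare_active / active if active else np.nan


def rare_active_summary(
    profile: PairedActivityProfile,
    abundance_threshold: float = 0.01,
    ratio_threshold: float = 1.0,
) -> RareActiveSummary:
    """Classify shared units into abundance x activity quadrants.

    The headline statistic is the fraction of above-ratio-threshold units
    that sit below the abundance threshold ("rare but active"); it is NaN if
    no unit exceeds the ratio threshold.
    """
    shared = profile.shared
    rare = shared["rel_rdna"] < abundance_threshold
    active = shared["ratio"] > ratio_threshold
    return RareActiveSummary(
        abundance_threshold, ratio_threshold,
        int((rare & active).sum()), int((~rare & active).sum()),
        int((rare & ~active).sum()), int((~rare & ~active).sum()),
    )


@dataclass
class RatioStats:
    """Pooled rRNA/rDNA ratio distribution over samples."""

    n: int
    mean: float
    sd: float
    min: float
    max: float
    fraction_below_1: float
    n_shared_only: int
    mean_shared_only: float
    fraction_below_1_shared_only: float
    n_phantom: int


def ratio_distribution_stats(
    profiles: Iterable[PairedActivityProfile],
) -> RatioStats:
    """Distribution of defined ratios pooled across samples.

    dna_only units (ratio 0) are included in the headline statistics and
    excluded from the ``*_shared_only`` variants, since whether ratio-0 units
    count toward "fraction below 1" is a reporting choice. Phantom units have
    no defined ratio; they are only counted.
    """
    all_ratios: list[np.ndarray] = []
    shared_ratios: list[np.ndarray] = []
    n_phantom = 0
    for p in profiles:
        defined = p.table["ratio"].dropna()
        all_ratios.append(defined.to_numpy(dtype=float))
        shared_ratios.append(p.shared["ratio"].to_numpy(dtype=float))
        n_phantom += int((p.table["presence_class"] == "phantom").sum())
    pooled = np.concatenate(all_ratios) if all_ratios else np.array([])
    shared = np.concatenate(shared_ratios) if shared_ratios else np.array([])
    if pooled.size == 0:
        raise ValueError("no defined ratios in the supplied profiles")
    return RatioStats(
        n=pooled.size,
        mean=float(pooled.mean()),
        sd=float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
        min=float(pooled.min()),
        max=float(pooled.max()),
        fraction_below_1=float((pooled < 1.0).mean()),
        n_shared_only=shared.size,
        mean_shared_only=float(shared.mean()) if shared.size else np.nan,
        fraction_below_1_shared_only=float((shared < 1.0).mean()) if shared.size else np.nan,
        n_phantom=n_phantom,
    )
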