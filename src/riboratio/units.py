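"""Taxonomic-unit formation from paired-pool amplicon reads.

Implements the read-level pipeline: expected-error quality filtering,
exact dereplication, greedy centroid clustering at 97% identity (OTUs),
abundance-skew denoising at single-nucleotide resolution (ZOTUs), read
mapping back to unit representatives, negative-control contaminant removal,
and cross-mapping of ZOTUs onto OTUs.

A read corpus is a mapping ``{(sample, pool): [Read, ...]}`` covering every
sample and pool that should share one unit set; units are always formed from
the pooled uniques across all samples and pools, as in studies that compare
rDNA against rRNA over a common unit space.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import levenshtein, max_edits_for_identity, pairwise_identity
from .seqio import Read

ColumnKey = tuple[str, str]  # (sample, pool)


# ---------------------------------------------------------------------------
# quality filtering


@dataclass
class FilterStats:
    n_input: int
    n_retained: int
    n_failed_length: int
    n_failed_ee: int

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_input if self.n_input else 0.0


_EE_CACHE: dict[str, float] = {}


def expected_errors(quality: str, phred_offset: int = 33) -> float:
    """Sum of per-base error probabilities 10^(-Q/10) for a quality string."""
    ee = _EE_CACHE.get(quality)
    if ee is None:
        ee = sum(10.0 ** (-(ord(ch) - phred_offset) / 10.0) for ch in quality)
        if len(_EE_CACHE) < 4096:  # bounded: real data has few distinct strings
            _EE_CACHE[quality] = ee
    return ee


def quality_filter(
    reads: Iterable[Read],
    min_len: int = 230,
    max_expected_error: float = 1.0,
    phred_offset: int = 33,
) -> tuple[list[Read], FilterStats]:
    """Retain reads with length >= min_len and expected errors <= the cap.

    Order is preserved. Returns the retained reads and counting stats
    (including the retained fraction).
    """
    kept: list[Read] = []
    n_input = n_len = n_ee = 0
    for i, read in enumerate(reads):
        n_input += 1
        if len(read.sequence) != len(read.quality):
            raise ValueError(f"malformed FASTQ record at index {i}: "
                             "sequence/quality length mismatch")
        if len(read.sequence) < min_len:
            n_len += 1
            continue
        if expected_errors(read.quality, phred_offset) > max_expected_error:
            n_ee += 1
            continue
        kept.append(read)
    return kept, FilterStats(n_input, len(kept), n_len, n_ee)


def filter_corpus(
    corpus: Mapping[ColumnKey, Sequence[Read]], **kwargs
) -> tuple[dict[ColumnKey, list[Read]], dict[ColumnKey, FilterStats]]:
    """Apply :func:`quality_filter` to every (sample, pool) read set."""
    filtered: dict[ColumnKey, list[Read]] = {}
    stats: dict[ColumnKey, FilterStats] = {}
    for key, reads in corpus.items():
        filtered[key], stats[key] = quality_filter(reads, **kwargs)
    return filtered, stats


# ---------------------------------------------------------------------------
# dereplication


@dataclass
class UniqueSequence:
    """A distinct full-length sequence with pooled size and provenance."""

    sequence: str
    size: int
    provenance: dict[ColumnKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.provenance and self.size != sum(self.provenance.values()):
            raise ValueError("size must equal the sum of provenance counts")


def dereplicate(corpus: Mapping[ColumnKey, Sequence[Read]]) -> list[UniqueSequence]:
    """Collapse exact full-length duplicates across all samples and pools.

    Output is sorted by decreasing pooled size, ties broken lexicographically
    by sequence -- the canonical input order for both unit formers.
    """
    per_column: dict[str, Counter] = defaultdict(Counter)
    for key, reads in corpus.items():
        counter = Counter(r.sequence for r in reads)
        for seq, n in counter.items():
            per_column[seq][key] = per_column[seq].get(key, 0) + n
    uniques = [
        UniqueSequence(seq, sum(prov.values()), dict(prov))
        for seq, prov in per_column.items()
    ]
    uniques.sort(key=lambda u: (-u.size, u.sequence))
    return uniques


# ---------------------------------------------------------------------------
# unit formation


@dataclass
class TaxonUnit:
    """An OTU or ZOTU: representative sequence plus member uniques."""

    unit_id: str
    method: str  # "OTU" | "ZOTU"
    representative: str
    members: list[UniqueSequence] = field(default_factory=list)

    @property
    def founder_size(self) -> int:
        return self.members[0].size if self.members else 0

    @property
    def total_size(self) -> int:
        return sum(m.size for m in self.members)


def greedy_cluster_otus(
    uniques: Sequence[UniqueSequence],
    identity_threshold: float = 0.97,
    minsize: int = 8,
) -> list[TaxonUnit]:
    """Greedy centroid clustering in decreasing-abundance order.

    Each unique joins the best existing centroid at identity >= threshold
    (highest identity; ties to the larger-founder, then earlier, centroid).
    Otherwise it founds a new centroid if its size >= minsize, and is dropped
    from centroid formation if smaller (it may still recruit reads during
    mapping). Centroid representatives are their founding unique's sequence,
    so centroids are pairwise below the threshold by construction.
    """
    units: list[TaxonUnit] = []
    for u in uniques:
        best: tuple[float, int, int] | None = None  # (identity, founder, -index)
        for idx, unit in enumerate(units):
            k = max_edits_for_identity(
                len(u.sequence), len(unit.representative), identity_threshold)
            ident = pairwise_identity(u.sequence, unit.representative, max_dist=k)
            if ident >= identity_threshold:
                key = (ident, unit.founder_size, -idx)
                if best is None or key > best:
                    best = key
        if best is not None:
            units[-best[2]].members.append(u)
        elif u.size >= minsize:
            units.append(TaxonUnit(f"OTU{len(units) + 1}", "OTU", u.sequence, [u]))
    return units


def unoise_denoise(
    uniques: Sequence[UniqueSequence],
    alpha: float = 2.0,
    minsize: int = 8,
) -> list[TaxonUnit]:
    """Abundance-skew denoising at single-nucleotide resolution.

    Uniques below ``minsize`` pooled reads are removed first. The remainder
    are scanned in decreasing-size order: a unique ``u`` merges into an
    accepted centroid ``c`` when its abundance skew ``size(u)/size(c)`` is at
    most ``beta(d) = 1 / 2**(alpha*d + 1)`` for edit distance
    ``d = levenshtein(u, c) >= 1`` -- the more edits away, the rarer a
    sequence must be to be explained as an error cloud of ``c``. Among
    qualifying centroids the one at smallest ``d`` wins (ties to larger size,
    then earlier). Non-merged uniques become new centroids; each centroid's
    representative is its own sequence.
    """
    units: list[TaxonUnit] = []
    for u in uniques:
        if u.size < minsize:
            continue
        best: tuple[int, int, int] | None = None  # (d, -size, index)
        for idx, unit in enumerate(units):
            size_c = unit.founder_size
            if u.size > size_c:  # skew > 1 can never satisfy beta(d) <= 1/4
                continue
            # skew <= beta(d)  <=>  d <= (log2(size_c/size_u) - 1) / alpha
            d_max = (math.log2(size_c / u.size) - 1.0) / alpha
            if d_max < 1.0:
                continue
            d = levenshtein(u.sequence, unit.representative, max_dist=int(d_max))
            if 1 <= d <= d_max:
                key = (d, -size_c, idx)
                if best is None or key < best:
                    best = key
        if best is not None:
            units[best[2]].members.append(u)
        else:
            units.append(TaxonUnit(f"ZOTU{len(units) + 1}", "ZOTU", u.sequence, [u]))
    return units


# ---------------------------------------------------------------------------
# read mapping


@dataclass
class CountTable:
    """Per-unit, per-(sample, pool) mapped read counts.

    ``counts`` is a unit x column integer DataFrame with a two-level column
    index (sample, pool); ``unassigned`` counts reads below the mapping
    identity threshold per column; ``input_reads`` is the number of filtered
    reads offered to the mapper per column.
    """

    counts: pd.DataFrame
    unassigned: pd.Series
    input_reads: pd.Series
    method: str

    @property
    def mapped_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def mapping_rate(self) -> pd.Series:
        return (self.mapped_totals / self.input_reads).fillna(0.0)

    def column(self, sample: str, pool: str) -> pd.Series:
        return self.counts[(sample, pool)]

    def to_tsv(self, path) -> None:
        flat = self.counts.copy()
        flat.columns = [f"{s}|{p}" for s, p in flat.columns]
        flat.rename_axis("unit_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, method: str = "OTU") -> "CountTable":
        flat = pd.read_csv(path, sep="\t", index_col=0)
        cols = pd.MultiIndex.from_tuples(
            [tuple(c.split("|", 1)) for c in flat.columns], names=["sample", "pool"])
        flat.columns = cols
        totals = flat.sum(axis=0)
        zero = pd.Series(0, index=cols)
        return cls(flat.astype(int), zero, totals, method)


def map_reads_to_units(
    corpus: Mapping[ColumnKey, Sequence[Read]],
    units: Sequence[TaxonUnit],
    min_identity: float,
) -> CountTable:
    """Assign every read to its best-identity representative above threshold.

    Ties go to the unit with the larger total size, then the earlier unit.
    Mapping is memoized per distinct read sequence, so cost scales with the
    number of uniques rather than reads. Reads below threshold to every
    representative are counted as unassigned.
    """
    if not units:
        raise ValueError("cannot map reads: unit list is empty")
    method = units[0].method
    rep_exact: dict[str, int] = {}
    for idx, unit in enumerate(units):
        rep_exact.setdefault(unit.representative, idx)
    order = sorted(range(len(units)),
                   key=lambda i: (-units[i].total_size, i))

    cache: dict[str, int] = {}

    def assign(seq: str) -> int:
        hit = cache.get(seq)
        if hit is not None:
            return hit
        exact = rep_exact.get(seq)
        if exact is not None:
            cache[seq] = exact
            return exact
        best: tuple[float, int, int] | None = None  # (identity, total, -idx)
        for idx in order:
            rep = units[idx].representative
            k = max_edits_for_identity(len(seq), len(rep), min_identity)
            ident = pairwise_identity(seq, rep, max_dist=k)
            if ident >= min_identity:
                key = (ident, units[idx].total_size, -idx)
                if best is None or key > best:
                    best = key
        result = -1 if best is None else -best[2]
        cache[seq] = result
        return result

    columns = sorted(corpus)
    col_index = pd.MultiIndex.from_tuples(columns, names=["sample", "pool"])
    counts = np.zeros((len(units), len(columns)), dtype=int)
    unassigned = np.zeros(len(columns), dtype=int)
    input_reads = np.zeros(len(columns), dtype=int)
    for j, key in enumerate(columns):
        seq_counts = Counter(r.sequence for r in corpus[key])
        input_reads[j] = sum(seq_counts.values())
        for seq, n in seq_counts.items():
            idx = assign(seq)
            if idx < 0:
                unassigned[j] += n
            else:
                counts[idx, j] += n
    frame = pd.DataFrame(counts, index=[u.unit_id for u in units], columns=col_index)
    return CountTable(
        frame,
        pd.Series(unassigned, index=col_index),
        pd.Series(input_reads, index=col_index),
        method,
    )


# ---------------------------------------------------------------------------
# contaminant removal and cross-mapping


def remove_contaminants(
    table: CountTable,
    negative_control_columns: Sequence[ColumnKey],
    threshold: float = 0.05,
    blacklist: Sequence[str] = (),
) -> tuple[CountTable, list[str]]:
    """Drop units averaging > threshold relative abundance in the controls.

    Each unit's relative abundance is computed within each negative-control
    column (a control with zero mapped reads contributes 0) and averaged
    across controls; units strictly above the threshold are removed from every
    column. ``blacklist`` accepts externally determined unit ids (e.g. from a
    reference chimera screen) to drop as well. Returns the reduced table and
    the dropped unit ids.
    """
    if not negative_control_columns:
        raise ValueError("need at least one negative-control column")
    rel = []
    for key in negative_control_columns:
        col = table.counts[tuple(key)]
        total = col.sum()
        rel.append(col / total if total > 0 else col * 0.0)
    mean_rel = pd.concat(rel, axis=1).mean(axis=1)
    drop = set(mean_rel.index[mean_rel > threshold]) | set(blacklist)
    dropped = [u for u in table.counts.index if u in drop]
    kept = table.counts.drop(index=dropped)
    return CountTable(kept, table.unassigned, table.input_reads, table.method), dropped


def map_zotus_to_otus(
    zotus: Sequence[TaxonUnit],
    otus: Sequence[TaxonUnit],
    identity_threshold: float = 0.97,
) -> pd.DataFrame:
    """Assign each ZOTU to its best-identity OTU representative >= threshold.

    Returns a frame indexed by zotu_id with columns ``otu_id`` (NA when
    unmapped) and ``identity``; per-OTU recruit counts are
    ``result["otu_id"].value_counts()``.
    """
    rows = []
    for z in zotus:
        best: tuple[float, int, int] | None = None
        for idx, o in enumerate(otus):
            k = max_edits_for_identity(
                len(z.representative), len(o.representative), identity_threshold)
            ident = pairwise_identity(z.representative, o.representative, max_dist=k)
            if ident >= identity_threshold:
                key = (ident, o.total_size, -idx)
                if best is None or key > best:
                    best = key
        if best is None:
            rows.append((z.unit_id, pd.NA, np.nan))
        else:
            rows.append((z.unit_id, otus[-best[2]].unit_id, best[0]))
    return pd.DataFrame(rows, columns=["zotu_id", "otu_id", "identity"]
                        ).set_index("zotu_id")


def representatives_fasta(units: Sequence[TaxonUnit]) -> list[tuple[str, str]]:
    """``(header, sequence)`` pairs in ``>unitID;size=N`` convention."""
    return [(f"{u.unit_id};size={u.total_size}", u.representative) for u in units]
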