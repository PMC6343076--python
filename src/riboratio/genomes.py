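"""Population-genome activity: abundance, transcription, and replication.

The genome side cross-validates the amplicon rRNA/rDNA ratio: relative
abundance comes from metagenome contig coverage, relative transcription from
summed ORF TPM over the metatranscriptome, their quotient is the genome-level
analog of the rRNA/rDNA ratio, and the iRep replication rate is estimated
independently from the origin-to-terminus coverage gradient. Inputs are plain
TSV tables (contigs, ORF counts, coverage windows); read alignment, assembly
and binning happen upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# table IO

CONTIG_COLUMNS = ["genome_id", "contig_id", "length", "mean_coverage"]
ORF_COLUMNS = ["orf_id", "genome_id", "length", "count"]
WINDOW_COLUMNS = ["genome_id", "window_index", "coverage"]


def _read_table(path, required: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return frame


def read_contig_table(path) -> pd.DataFrame:
    return _read_table(path, CONTIG_COLUMNS)


def read_orf_table(path) -> pd.DataFrame:
    return _read_table(path, ORF_COLUMNS)


def read_coverage_windows(path) -> pd.DataFrame:
    return _read_table(path, WINDOW_COLUMNS)


# ---------------------------------------------------------------------------
# abundance and transcription


def genome_relative_abundance(
    contigs: pd.DataFrame, total_reads: int, normalize: bool = True
) -> pd.Series:
    """Per-genome relative abundance from contig coverage.

    Raw value: length-weighted mean contig coverage divided by the total
    metagenome read count. With ``normalize`` (default) the raw values are
    rescaled to sum to 1 across genomes, making the transcription/abundance
    ratio a fraction-over-fraction like the amplicon side.
    """
    if total_reads <= 0:
        raise ValueError("total metagenome reads must be positive")
    if (contigs["length"] <= 0).any():
        raise ValueError("contig lengths must be positive")
    if (contigs["mean_coverage"] < 0).any():
        raise ValueError("coverages must be non-negative")

    def weighted_mean(group: pd.DataFrame) -> float:
        return float(np.average(group["mean_coverage"], weights=group["length"]))

    raw = contigs.groupby("genome_id").apply(weighted_mean, include_groups=False)
    raw = raw / total_reads
    if normalize:
        total = raw.sum()
        if total <= 0:
            raise ValueError("all genomes have zero coverage")
        return raw / total
    return raw


def orf_tpm(orfs: pd.DataFrame) -> pd.Series:
    """Transcripts-per-million per ORF: length-normalized rates scaled to 1e6."""
    if (orfs["length"] < 1).any():
        raise ValueError("ORF lengths must be >= 1")
    rate = orfs["count"] / (orfs["length"] / 1000.0)
    total = rate.sum()
    if total <= 0:
        raise ValueError("no mapped transcript reads (sum of rates is 0)")
    tpm = 1e6 * rate / total
    tpm.index = orfs["orf_id"]
    return tpm


def genome_relative_transcription(
    tpm: pd.Series, membership: pd.Series
) -> pd.Series:
    """Per-genome fraction of community transcription: summed ORF TPM / 1e6.

    ``membership`` maps orf_id to genome_id (NA for unbinned ORFs, which
    contribute to the TPM denominator but to no genome, so fractions sum to
    at most 1). An ORF claimed twice raises.
    """
    if membership.index.has_duplicates:
        dup = membership.index[membership.index.duplicated()].tolist()
        raise ValueError(f"ORFs claimed by more than one genome: {dup}")
    joined = pd.DataFrame({"tpm": tpm, "genome_id": membership.reindex(tpm.index)})
    binned = joined.dropna(subset=["genome_id"])
    fractions = binned.groupby("genome_id")["tpm"].sum() / 1e6
    return fractions


def transcription_abundance_ratio(
    abundance: pd.Series, transcription: pd.Series
) -> pd.DataFrame:
    """Transcription/abundance ratio per genome (genome-side rRNA/rDNA analog).

    Genomes with zero abundance but positive transcription are flagged
    (the genome analog of phantom taxa) and carry a NaN ratio.
    """
    genomes = abundance.index.union(transcription.index)
    ab = abundance.reindex(genomes).fillna(0.0)
    tr = transcription.reindex(genomes).fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ab > 0, tr / ab.replace(0, np.nan), np.nan)
    out = pd.DataFrame(
        {"rel_abundance": ab, "rel_transcription": tr, "ratio": ratio,
         "phantom_like": (ab == 0) & (tr > 0)},
        index=genomes,
    )
    return out


# ---------------------------------------------------------------------------
# iRep replication rate


@dataclass
class IrepResult:
    """Replication-rate estimate from the sorted-coverage log-linear fit."""

    irep: float
    r_squared: float
    slope_log2: float
    n_windows_used: int

    def summary(self) -> str:
        return (f"iRep = {self.irep:.3f} (log2 span {self.slope_log2:.3f}, "
                f"R^2 = {self.r_squared:.3f}, {self.n_windows_used} windows)")


def irep_estimate(
    coverage_windows: np.ndarray | pd.Series,
    trim_fraction: float = 0.05,
    min_windows: int = 50,
) -> IrepResult:
    """Index of replication from the genome coverage gradient.

    Zero-coverage windows are discarded; the remaining window coverages are
    sorted ascending and assigned normalized ranks in [0, 1]; after trimming
    ``trim_fraction`` of windows from each end, ordinary least squares fits
    log2(coverage) against rank, and iRep is 2 to the fitted span between
    rank 1 and rank 0 (the origin-to-terminus coverage fold change). The R^2
    of the fit is a quality diagnostic. All-equal coverages return exactly 1.
    """
    cov = np.asarray(coverage_windows, dtype=float)
    cov = cov[cov > 0]
    if cov.size < min_windows:
        raise ValueError(
            f"need >= {min_windows} non-zero coverage windows, have {cov.size}")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    cov = np.sort(cov)
    n = cov.size
    if np.all(cov == cov[0]):
        return IrepResult(1.0, 1.0, 0.0, n)
    ranks = np.arange(n) / (n - 1)
    k = int(np.floor(trim_fraction * n))
    use = slice(k, n - k if k else n)
    x, y = ranks[use], np.log2(cov[use])
    fit = stats.linregress(x, y)
    span = fit.slope  # fitted value at rank 1 minus rank 0
    return IrepResult(
        float(2.0 ** span), float(fit.rvalue ** 2), float(span), n)


def irep_abundance_pattern(
    activities: pd.DataFrame, abundance_threshold: float = 0.01
) -> tuple[float, float, pd.DataFrame]:
    """Correlation of iRep with the transcription/abundance ratio + quadrants.

    ``activities`` needs columns irep, ratio, rel_abundance. Returns
    (pearson_r, p_value, quadrant table of high/low iRep against
    above/below the abundance threshold); the correlation is NaN when
    either metric is constant.
    """
    rows = activities.dropna(subset=["irep", "ratio"])
    if len(rows) < 3:
        raise ValueError("need >= 3 genomes with both iRep and ratio")
    if rows["irep"].nunique() < 2 or rows["ratio"].nunique() < 2:
        r, p = np.nan, np.nan
    else:
        r, p = stats.pearsonr(rows["irep"], rows["ratio"])
    high_irep = rows["irep"] > rows["irep"].median()
    rare = rows["rel_abundance"] < abundance_threshold
    quadrants = pd.DataFrame(
        {"rare": [(high_irep & rare).sum(), (~high_irep & rare).sum()],
         "abundant": [(high_irep & ~rare).sum(), (~high_irep & ~rare).sum()]},
        index=["high_irep", "low_irep"],
    )
    return float(r), float(p), quadrants
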