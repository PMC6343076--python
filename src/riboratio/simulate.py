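"""Ground-truthed synthetic paired rDNA/rRNA communities.

The generator emulates the data-generating process the downstream analysis
assumes: a community of taxa with lognormal abundances ``p_t``, per-cell
ribosomal amplification factors ``a_t`` (the latent "activity" the rRNA/rDNA
ratio estimates), and 16S copy numbers ``c_t``. The rDNA amplicon pool samples
taxa proportionally to ``p_t * c_t``; the rRNA pool proportionally to
``p_t * c_t * a_t``. Reads are single-end with independent per-base
substitution errors: a PCR/sequencing rate applied to both pools, plus a
reverse-transcriptase rate applied to rRNA reads only (defaults 1/20,000 and
1/15,000 per base, the scale reported for Taq and RT enzymes). A genome-side
generator emits window coverage encoding a true replication rate and per-ORF
transcript counts encoding true transcription weights.

Everything is driven by numpy Generators seeded from the scenario seed, so a
scenario reproduces bit-for-bit.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .align import levenshtein
from .seqio import Read, TRUTH_DELIMITER

BASES = np.frombuffer(b"ACGT", dtype="S1")
POOLS = ("rDNA", "rRNA")


def _stream_seed(seed: int, *tags: object) -> np.random.Generator:
    """Deterministic child generator for a named stream of a scenario seed."""
    words = [int(seed) & 0x7FFFFFFF]
    for tag in tags:
        words.append(zlib.crc32(str(tag).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one simulated paired-pool sequencing experiment.

    Rates are per base per read; ``rt_error_rate`` applies to rRNA reads on
    top of ``sub_error_rate``. Error model is substitution-only by default
    (``indel_rate=0``), keeping edit-distance-1 structure clean. Quality
    scores are a single constant Phred value, sufficient for an
    expected-error filter.
    """

    n_taxa: int = 150
    seq_len: int = 250
    mean_divergence: float = 0.05
    abundance_sigma: float = 1.5
    activity_model: str = "independent"  # or "kill_the_winner"
    activity_sigma: float = 1.0
    copy_number_max: int = 1
    depth_rdna: int = 50_000
    depth_rrna: int = 50_000
    sub_error_rate: float = 1.0 / 20_000
    rt_error_rate: float = 1.0 / 15_000
    indel_rate: float = 0.0
    phred_offset: int = 33
    quality: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.seq_len < 150:
            raise ValueError("seq_len must be >= 150")
        if not 0 < self.mean_divergence < 0.3:
            raise ValueError("mean_divergence must be in (0, 0.3)")
        for name in ("sub_error_rate", "rt_error_rate", "indel_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 0.1:
                raise ValueError(f"{name} must be in [0, 0.1]")
        if self.depth_rdna < 0 or self.depth_rrna < 0:
            raise ValueError("depths must be >= 0")
        if self.activity_model not in ("independent", "kill_the_winner"):
            raise ValueError(f"unknown activity_model {self.activity_model!r}")
        if self.abundance_sigma < 0 or self.activity_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if self.copy_number_max < 1:
            raise ValueError("copy_number_max must be >= 1")

    def depth(self, pool: str) -> int:
        return self.depth_rdna if pool == "rDNA" else self.depth_rrna

    def error_rate(self, pool: str) -> float:
        return self.sub_error_rate + (self.rt_error_rate if pool == "rRNA" else 0.0)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimScenario":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class TrueCommunity:
    """Ground truth: abundances, activities, copy numbers, references, tree."""

    taxon_ids: list[str]
    abundances: np.ndarray
    activities: np.ndarray
    copy_numbers: np.ndarray
    references: list[str]
    tree: TreeNode

    def __post_init__(self) -> None:
        n = len(self.taxon_ids)
        self.abundances = np.asarray(self.abundances, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        self.copy_numbers = np.asarray(self.copy_numbers, dtype=int)
        if not (len(self.abundances) == len(self.activities)
                == len(self.copy_numbers) == len(self.references) == n):
            raise ValueError("field lengths disagree")
        if abs(self.abundances.sum() - 1.0) > 1e-12:
            raise ValueError("abundances must sum to 1")
        if np.any(self.activities <= 0):
            raise ValueError("activities must be positive")
        if len(set(self.references)) != n:
            raise ValueError("reference sequences must be pairwise distinct")
        tips = sorted(t.name for t in self.tree.tips())
        if tips != sorted(self.taxon_ids):
            raise ValueError("tree tips must match taxon_ids exactly")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"taxon_id": self.taxon_ids, "abundance": self.abundances,
             "activity": self.activities, "copy_number": self.copy_numbers}
        ).set_index("taxon_id")

    def write_truth_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def write_tree(self, path) -> None:
        self.tree.write(str(path), format="newick")

    def newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


@dataclass(frozen=True)
class GenomeTruth:
    """Ground truth for one population genome's coverage and transcription."""

    genome_length: int = 2_000_000
    window: int = 5_000
    true_irep: float = 2.0
    mean_coverage: float = 20.0
    read_length: int = 150
    orf_lengths: tuple[int, ...] = (900,) * 50
    orf_weights: tuple[float, ...] = (1.0,) * 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_irep < 1.0:
            raise ValueError("true_irep must be >= 1")
        if self.genome_length % self.window != 0:
            raise ValueError("window must divide genome_length cleanly")
        if self.genome_length // self.window < 50:
            raise ValueError("need at least 50 coverage windows")
        if len(self.orf_lengths) != len(self.orf_weights):
            raise ValueError("orf_lengths and orf_weights must align")
        if any(l < 100 for l in self.orf_lengths):
            raise ValueError("orf_lengths must be >= 100 bp")
        if sum(self.orf_weights) <= 0:
            raise ValueError("orf_weights must have positive total")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be >= 0")

    @property
    def n_windows(self) -> int:
        return self.genome_length // self.window


# ---------------------------------------------------------------------------
# reference sequences and tree


def _random_topology(taxon_ids: Sequence[str], rng: np.random.Generator) -> TreeNode:
    """Random bifurcating rooted topology with Exp(1) branch lengths."""
    nodes = [TreeNode(name=t) for t in taxon_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        left.length = float(rng.exponential(1.0))
        right.length = float(rng.exponential(1.0))
        nodes.append(TreeNode(children=[left, right]))
    root = nodes[0]
    root.length = None
    return root


def _mutate(seq: np.ndarray, n_events: int, rng: np.random.Generator) -> np.ndarray:
    """Apply ``n_events`` point substitutions (uniform site, uniform new base)."""
    out = seq.copy()
    if n_events == 0:
        return out
    sites = rng.integers(0, len(seq), size=n_events)
    for pos in sites:
        current = out[pos]
        choices = BASES[BASES != current]
        out[pos] = choices[rng.integers(0, 3)]
    return out


def simulate_references(
    n_taxa: int,
    seq_len: int,
    mean_divergence: float = 0.05,
    seed: int = 0,
    max_attempts: int = 100,
    min_taxon_distance: int = 8,
) -> tuple[list[str], TreeNode]:
    """Evolve distinct 16S-like references down a random bifurcating tree.

    A random root sequence is evolved along each branch with a Poisson number
    of point substitutions proportional to branch length (sites drawn
    uniformly with replacement, so per-site events are the Jukes-Cantor jump
    process). Branch lengths are rescaled so the mean pairwise patristic
    distance equals ``mean_divergence`` substitutions per site. Tips are
    labelled ``T001..`` and returned with the rooted tree.

    References are kept at least ``min_taxon_distance`` edits apart (extra
    substitutions are applied to tips of too-close pairs): the taxa are
    distinct populations, not strain microvariants of one another, matching
    the separation the single-nucleotide denoiser assumes between true
    biological sequences. Set it to 1 to enforce bare distinctness only.

    Raises ``RuntimeError`` if separated sequences cannot be produced within
    ``max_attempts * n_taxa`` corrective substitutions (e.g. divergence 0
    forces duplicates).
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if seq_len < 150:
        raise ValueError("seq_len must be >= 150")
    if not 0 <= mean_divergence < 0.3:
        raise ValueError("mean_divergence must be in [0, 0.3)")
    rng = _stream_seed(seed, "references")
    width = max(3, len(str(n_taxa)))
    taxon_ids = [f"T{i + 1:0{width}d}" for i in range(n_taxa)]
    tree = _random_topology(taxon_ids, rng)

    # rescale branch lengths so mean pairwise tip-tip distance = mean_divergence
    dm = tree.tip_tip_distances()
    mean_path = dm.data[np.triu_indices(n_taxa, k=1)].mean()
    scale = mean_divergence / mean_path if mean_path > 0 else 0.0
    for node in tree.traverse(include_self=False):
        node.length = (node.length or 0.0) * scale

    root_seq = rng.choice(BASES, size=seq_len)
    sequences: dict[str, np.ndarray] = {}

    def evolve(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            n_sub = int(rng.poisson(child.length * seq_len))
            child_seq = _mutate(seq, n_sub, rng)
            if child.is_tip():
                sequences[child.name] = child_seq
            else:
                evolve(child, child_seq)

    evolve(tree, root_seq)

    def as_str(arr: np.ndarray) -> str:
        return arr.tobytes().decode()

    # enforce the separation floor by adding substitutions to too-close tips
    floor = max(1, int(min_taxon_distance))
    budget = max_attempts * n_taxa
    fixes = 0
    dirty = True
    while dirty:
        dirty = False
        strings = {t: as_str(sequences[t]) for t in taxon_ids}
        for i in range(n_taxa):
            for j in range(i + 1, n_taxa):
                a, b = taxon_ids[i], taxon_ids[j]
                if levenshtein(strings[a], strings[b], max_dist=floor - 1) < floor:
                    if mean_divergence == 0 or fixes >= budget:
                        raise RuntimeError(
                            "could not produce distinct, separated reference "
                            "sequences; increase mean_divergence or seq_len"
                        )
                    sequences[b] = _mutate(sequences[b], 1, rng)
                    strings[b] = as_str(sequences[b])
                    fixes += 1
                    dirty = True

    references = [as_str(sequences[t]) for t in taxon_ids]
    return references, tree


# ---------------------------------------------------------------------------
# community composition


def simulate_community(scenario: SimScenario) -> TrueCommunity:
    """Draw a ground-truth community under the scenario.

    Abundances are lognormal(0, abundance_sigma) normalized to sum 1.
    Activities are lognormal(0, activity_sigma): independent of abundance
    under the ``independent`` model, or rank-inverted against abundance under
    ``kill_the_winner`` (fast growers kept rare by lysis/grazing), with mild
    multiplicative jitter so the anti-correlation is strong but not exactly -1.
    """
    references, tree = simulate_references(
        scenario.n_taxa, scenario.seq_len, scenario.mean_divergence,
        seed=scenario.seed,
    )
    rng = _stream_seed(scenario.seed, "community")
    n = scenario.n_taxa
    p = rng.lognormal(0.0, scenario.abundance_sigma, size=n)
    p /= p.sum()
    a = rng.lognormal(0.0, scenario.activity_sigma, size=n)
    if scenario.activity_model == "kill_the_winner":
        # most-abundant taxon gets the smallest activity, then jitter
        order = np.argsort(np.argsort(p))          # ranks of p, 0 = smallest
        a = np.sort(a)[::-1][order]                 # descending a onto ascending p rank
        a = a * rng.lognormal(0.0, 0.2 * scenario.activity_sigma, size=n)
    if scenario.copy_number_max > 1:
        c = rng.integers(1, scenario.copy_number_max + 1, size=n)
    else:
        c = np.ones(n, dtype=int)
    width = max(3, len(str(n)))
    taxon_ids = [f"T{i + 1:0{width}d}" for i in range(n)]
    return TrueCommunity(taxon_ids, p, a, c, references, tree)


def expected_pool_fractions(community: TrueCommunity, pool: str) -> np.ndarray:
    """True per-taxon read fractions for one amplicon pool.

    rDNA fractions are proportional to ``p_t * c_t`` (gene copies); rRNA
    fractions to ``p_t * c_t * a_t`` (transcripts). The per-taxon ratio of the
    two fractions is ``a_t`` divided by the community constant
    ``sum(p c a) / sum(p c)`` -- the quantity the rRNA/rDNA estimator recovers.
    """
    if pool not in POOLS:
        raise ValueError(f"pool must be one of {POOLS}")
    w = community.abundances * community.copy_numbers
    if pool == "rRNA":
        w = w * community.activities
    return w / w.sum()


# ---------------------------------------------------------------------------
# read sampling


def _mutate_read(seq_bytes: np.ndarray, n_err: int, rng: np.random.Generator) -> str:
    out = seq_bytes.copy()
    positions = rng.choice(len(out), size=n_err, replace=False)
    for pos in positions:
        choices = BASES[BASES != out[pos]]
        out[pos] = choices[rng.integers(0, 3)]
    return out.tobytes().decode()


def sample_amplicon_reads(
    community: TrueCommunity,
    pool: str,
    scenario: SimScenario,
    sample: str = "S1",
) -> list[Read]:
    """Draw one sample's single-end reads for one pool as FASTQ-ready records.

    Taxon of origin is multinomial over :func:`expected_pool_fractions`; each
    read is its taxon's reference with independent per-base substitutions at
    the pool's error rate (a substituted base always changes, so the realized
    mismatch fraction equals the rate). Qualities are constant Phred
    ``scenario.quality``. Headers are ``{sample}|{pool}|{i};truth={taxon}``;
    the truth suffix is for tests only. Depth 0 yields an empty read list.
    """
    fractions = expected_pool_fractions(community, pool)
    depth = scenario.depth(pool)
    rng = _stream_seed(scenario.seed, "reads", sample, pool)
    counts = rng.multinomial(depth, fractions)
    err = scenario.error_rate(pool)
    qual = chr(scenario.phred_offset + scenario.quality) * scenario.seq_len
    reads: list[Read] = []
    for t_idx in np.nonzero(counts)[0]:
        tid = community.taxon_ids[t_idx]
        ref = community.references[t_idx]
        n_t = int(counts[t_idx])
        prefix = f"{sample}|{pool}|"
        suffix = f"{TRUTH_DELIMITER}{tid}"
        if err == 0.0:
            reads.extend(
                Read(f"{prefix}{len(reads) + k}{suffix}", ref, qual)
                for k in range(n_t)
            )
            continue
        ref_bytes = np.frombuffer(ref.encode(), dtype="S1")
        n_errors = rng.binomial(scenario.seq_len, err, size=n_t)
        for k in range(n_t):
            seq = ref if n_errors[k] == 0 else _mutate_read(ref_bytes, n_errors[k], rng)
            reads.append(Read(f"{prefix}{len(reads)}{suffix}", seq, qual))
    rng.shuffle(reads)
    return reads


def sample_paired_pools(
    community: TrueCommunity, scenario: SimScenario, sample: str = "S1"
) -> dict[tuple[str, str], list[Read]]:
    """Both pools of one sample, keyed by ``(sample, pool)``."""
    return {
        (sample, pool): sample_amplicon_reads(community, pool, scenario, sample)
        for pool in POOLS
    }


def simulate_negative_control(
    contaminant_refs: Sequence[str],
    depth: int,
    seed: int = 0,
    proportions: Sequence[float] | None = None,
    sample: str = "NC1",
    pool: str = "rDNA",
    quality: int = 30,
    phred_offset: int = 33,
) -> list[Read]:
    """Blank-extraction control reads drawn from contaminant references.

    Error-free by design: the control exercises the >5%-of-control-reads
    contaminant rule, not the error model.
    """
    if len(contaminant_refs) == 0:
        raise ValueError("need at least one contaminant reference")
    rng = _stream_seed(seed, "negcontrol", sample)
    if proportions is None:
        probs = np.full(len(contaminant_refs), 1.0 / len(contaminant_refs))
    else:
        probs = np.asarray(proportions, dtype=float)
        probs = probs / probs.sum()
    counts = rng.multinomial(depth, probs)
    reads: list[Read] = []
    for j, ref in enumerate(contaminant_refs):
        qual = chr(phred_offset + quality) * len(ref)
        suffix = f"{TRUTH_DELIMITER}contam{j + 1}"
        reads.extend(
            Read(f"{sample}|{pool}|{len(reads) + k}{suffix}", ref, qual)
            for k in range(int(counts[j]))
        )
    rng.shuffle(reads)
    return reads


# ---------------------------------------------------------------------------
# genome-side truth


def simulate_genome_coverage(genome_truth: GenomeTruth) -> np.ndarray:
    """Per-window mean read coverage with a replication gradient.

    Expected read-start density at genome fraction ``x`` (origin at 0) is
    proportional to ``2 ** (log2(true_irep) * (1 - x))``: coverage at the
    origin is ``true_irep`` times coverage at the terminus. The number of
    reads starting in each window is Poisson with the density scaled so mean
    per-base coverage over the genome equals ``mean_coverage``; window
    coverage is ``reads * read_length / window``. A 5 kb window at 20x
    coverage therefore averages hundreds of reads, so its relative noise is a
    few percent -- the regime in which coverage-gradient replication
    estimates are meaningful.
    """
    rng = _stream_seed(genome_truth.seed, "coverage")
    n = genome_truth.n_windows
    x = (np.arange(n) + 0.5) / n
    density = 2.0 ** (np.log2(genome_truth.true_irep) * (1.0 - x))
    reads_per_window = (genome_truth.mean_coverage * genome_truth.window
                        / genome_truth.read_length)
    lam = reads_per_window * density / density.mean()
    counts = rng.poisson(lam)
    return counts * genome_truth.read_length / genome_truth.window


def simulate_orf_transcripts(
    genome_truth: GenomeTruth, total_reads: int, seed: int | None = None
) -> np.ndarray:
    """Multinomial per-ORF read counts, length-proportional sampling.

    Sampling probabilities are proportional to ``weight * length`` so that
    length-normalized TPM recovers the configured transcription weights.
    """
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    rng = _stream_seed(genome_truth.seed if seed is None else seed, "orfs")
    w = np.asarray(genome_truth.orf_weights, dtype=float)
    l = np.asarray(genome_truth.orf_lengths, dtype=float)
    probs = w * l
    probs = probs / probs.sum()
    return rng.multinomial(int(total_reads), probs)


def coverage_frame(genome_id: str, coverage: np.ndarray) -> pd.DataFrame:
    """Coverage vector as the pipeline's window-table layout."""
    return pd.DataFrame(
        {"genome_id": genome_id, "window_index": np.arange(len(coverage)),
         "coverage": coverage}
    )


def orf_frame(genome_id: str, genome_truth: GenomeTruth, counts: np.ndarray) -> pd.DataFrame:
    """ORF counts as the pipeline's ORF-table layout."""
    n = len(counts)
    return pd.DataFrame(
        {"orf_id": [f"{genome_id}_orf{i + 1}" for i in range(n)],
         "genome_id": genome_id,
         "length": list(genome_truth.orf_lengths),
         "count": counts}
    )
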