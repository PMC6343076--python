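"""Alpha diversity, UniFrac, ordination, and PERMANOVA.

Conventions fixed here (they shift absolute values and are easy to get
silently wrong across toolkits): Shannon entropy in bits (log2; natural log
by flag), Faith's PD root-inclusive (the path from every observed tip up to
the root is counted), weighted UniFrac non-normalized by default, PCoA axis
proportions over positive eigenvalues only, PERMANOVA p-values with the +1
convention. Trees are scikit-bio ``TreeNode`` objects throughout.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .units import CountTable

# ---------------------------------------------------------------------------
# alpha diversity


def richness(counts: np.ndarray | pd.Series) -> int:
    return int((np.asarray(counts) > 0).sum())


def shannon(counts: np.ndarray | pd.Series, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log p_i over positive entries.

    Defaults to bits (base 2); pass ``base=np.e`` for nats.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or c.sum() <= 0:
        raise ValueError("need at least one positive count")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    p = c[c > 0]
    p = p / p.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum())


def faith_pd(tree: TreeNode, observed_tips: Sequence[str]) -> float:
    """Faith's phylogenetic diversity, root-inclusive.

    Sum of branch lengths of the minimal subtree connecting the observed tips
    *and the root*, i.e. the union of every observed tip's path to the root.
    """
    observed = set(observed_tips)
    if not observed:
        raise ValueError("observed_tips must be non-empty")
    tip_names = {t.name for t in tree.tips()}
    unknown = observed - tip_names
    if unknown:
        raise KeyError(f"tips not in tree: {sorted(unknown)}")
    total = 0.0
    # postorder flag: does this subtree contain an observed tip?
    has_observed: dict[int, bool] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            flag = node.name in observed
        else:
            flag = any(has_observed[id(ch)] for ch in node.children)
        has_observed[id(node)] = flag
        if flag and node.parent is not None:
            total += node.length or 0.0
    return total


_ALPHA_METRICS: dict[str, Callable] = {
    "richness": lambda counts, tips, tree: richness(counts),
    "shannon": lambda counts, tips, tree: shannon(counts),
    "faith_pd": lambda counts, tips, tree: faith_pd(
        tree, [t for t, c in zip(tips, counts) if c > 0]),
}


def rarefy_mean_alpha(
    table: CountTable | pd.DataFrame,
    metric: str,
    depth: int,
    n_reps: int = 10,
    seed: int | None = None,
    tree: TreeNode | None = None,
) -> pd.Series:
    """Mean alpha diversity over repeated rarefactions to a fixed depth.

    Every column is subsampled without replacement to ``depth`` reads
    ``n_reps`` times; the metric ("richness", "shannon" or "faith_pd", the
    latter requiring ``tree``) is averaged over repetitions. Columns whose
    totals fall below ``depth`` raise, listing the offenders.
    """
    counts = table.counts if isinstance(table, CountTable) else table
    if metric not in _ALPHA_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_ALPHA_METRICS)}")
    if metric == "faith_pd" and tree is None:
        raise ValueError("faith_pd requires a tree")
    totals = counts.sum(axis=0)
    shallow = [str(c) for c in counts.columns[totals < depth]]
    if shallow:
        raise ValueError(f"columns below rarefaction depth {depth}: {shallow}")
    rng = np.random.default_rng(seed)
    fn = _ALPHA_METRICS[metric]
    tips = list(counts.index)
    out = {}
    for col in counts.columns:
        vec = counts[col].to_numpy(dtype=np.int64)
        values = [
            fn(rng.multivariate_hypergeometric(vec, depth), tips, tree)
            for _ in range(n_reps)
        ]
        out[col] = float(np.mean(values))
    return pd.Series(out)


# ---------------------------------------------------------------------------
# tree construction


def _kmer_profile(seq: str, k: int) -> dict[str, int]:
    prof: dict[str, int] = defaultdict(int)
    for i in range(len(seq) - k + 1):
        prof[seq[i:i + k]] += 1
    return dict(prof)


def kmer_cosine_distance(a: str, b: str, k: int = 6) -> float:
    """1 - cosine similarity of overlapping k-mer count profiles."""
    pa, pb = _kmer_profile(a, k), _kmer_profile(b, k)
    dot = sum(n * pb.get(kmer, 0) for kmer, n in pa.items())
    na = np.sqrt(sum(n * n for n in pa.values()))
    nb = np.sqrt(sum(n * n for n in pb.values()))
    if na == 0 or nb == 0:
        return 1.0
    d = 1.0 - dot / (na * nb)
    return 0.0 if d < 1e-12 else float(d)


def build_unit_tree(
    representatives: Mapping[str, str] | Sequence[tuple[str, str]], k: int = 6
) -> TreeNode:
    """Phylogeny over unit representatives: k-mer distance + neighbor joining.

    Accepts an id->sequence mapping or (id, sequence) pairs. Pairwise
    distances are 1 - cosine similarity of k-mer profiles; the NJ tree is
    midpoint-rooted and negative NJ branch lengths are clamped to 0. This is
    deliberately lightweight scaffolding for PD/UniFrac when no externally
    built tree is supplied; any user newick overrides it.
    """
    if not isinstance(representatives, Mapping):
        pairs = list(representatives)
        ids = [i for i, _ in pairs]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sequence ids")
        representatives = dict(pairs)
    ids = list(representatives)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = kmer_cosine_distance(representatives[ids[i]],
                                     representatives[ids[j]], k)
            dm[i, j] = dm[j, i] = d
    if n == 2:
        half = dm[0, 1] / 2.0
        return TreeNode(children=[TreeNode(name=ids[0], length=half),
                                  TreeNode(name=ids[1], length=half)])
    tree = nj(DistanceMatrix(dm, ids))
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    total = sum((node.length or 0.0) for node in tree.traverse(include_self=False))
    if total > 0:
        tree = tree.root_at_midpoint()
    else:  # all-zero branch lengths (identical sequences): arbitrary root
        tree = tree.root_at(tree.children[0]) if tree.children else tree
    return tree


# ---------------------------------------------------------------------------
# UniFrac


def _branch_flows(
    tree: TreeNode, samples: Sequence[Mapping[str, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch lengths and per-sample descendant-read fractions.

    Returns (lengths[b], flows[s, b]) over all non-root branches, where
    ``flows[s, b]`` is the fraction of sample s's reads on tips below branch
    b. Raises on sample tips missing from the tree.
    """
    tip_names = {t.name for t in tree.tips()}
    totals = []
    for s in samples:
        present = {k for k, v in s.items() if v > 0}
        missing = present - tip_names
        if missing:
            raise KeyError(f"sample tips not in tree: {sorted(missing)}")
        total = sum(v for v in s.values() if v > 0)
        if total <= 0:
            raise ValueError("each sample needs positive total abundance")
        totals.append(total)
    lengths: list[float] = []
    flows: list[np.ndarray] = []
    subtree_sum: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = np.array([s.get(node.name, 0.0) for s in samples], dtype=float)
            vec[vec < 0] = 0.0
        else:
            vec = np.sum([subtree_sum[id(ch)] for ch in node.children], axis=0)
        subtree_sum[id(node)] = vec
        if node.parent is not None:
            lengths.append(node.length or 0.0)
            flows.append(vec / np.asarray(totals))
    return np.asarray(lengths), np.asarray(flows).T


def unifrac(
    tree: TreeNode,
    sample_a: Mapping[str, float],
    sample_b: Mapping[str, float],
    weighted: bool = False,
    normalized: bool = False,
) -> float:
    """UniFrac distance between two abundance vectors over tree tips.

    Unweighted: fraction of branch length unique to one sample among branch
    length covered by either (in [0, 1]). Weighted: sum over branches of
    length times |flow_A - flow_B|, where flow is the fraction of a sample's
    reads descending through the branch; non-normalized by default, or
    divided by the same sum with flows replaced by their sums when
    ``normalized``.
    """
    lengths, flows = _branch_flows(tree, [sample_a, sample_b])
    fa, fb = flows[0], flows[1]
    if weighted:
        d = float(np.sum(lengths * np.abs(fa - fb)))
        if normalized:
            denom = float(np.sum(lengths * (fa + fb)))
            d = d / denom if denom > 0 else 0.0
        return d
    pa, pb = fa > 0, fb > 0
    denom = float(np.sum(lengths * np.maximum(pa, pb)))
    if denom == 0:
        return 0.0
    return float(np.sum(lengths * (pa ^ pb)) / denom)


def unifrac_matrix(
    abundances: pd.DataFrame,
    tree: TreeNode,
    weighted: bool = False,
    normalized: bool = False,
) -> DistanceMatrix:
    """All-pairs UniFrac over the columns of a units x samples frame."""
    ids = [str(c) for c in abundances.columns]
    samples = [abundances[c].to_dict() for c in abundances.columns]
    lengths, flows = _branch_flows(tree, samples)
    n = len(ids)
    out = np.zeros((n, n))
    pres = flows > 0
    for i in range(n):
        for j in range(i + 1, n):
            if weighted:
                d = float(np.sum(lengths * np.abs(flows[i] - flows[j])))
                if normalized:
                    denom = float(np.sum(lengths * (flows[i] + flows[j])))
                    d = d / denom if denom > 0 else 0.0
            else:
                denom = float(np.sum(lengths * np.maximum(pres[i], pres[j])))
                d = float(np.sum(lengths * (pres[i] ^ pres[j])) / denom) if denom else 0.0
            out[i, j] = out[j, i] = d
    return DistanceMatrix(out, ids)


# ---------------------------------------------------------------------------
# ordination


@dataclass
class PCoAResult:
    """Principal-coordinate embedding of a distance matrix."""

    coordinates: pd.DataFrame       # samples x axes, ordered by eigenvalue
    eigenvalues: np.ndarray         # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # lambda_i / sum(positive lambdas)


def pcoa(distance_matrix: DistanceMatrix | np.ndarray,
         ids: Sequence[str] | None = None) -> PCoAResult:
    """Classical MDS: Gower-center -D^2/2, eigendecompose, order by eigenvalue.

    Axis proportions are eigenvalues over the sum of *positive* eigenvalues;
    negative eigenvalues (non-Euclidean input) are reported, not corrected.
    Coordinates are returned for axes with positive eigenvalues.
    """
    if isinstance(distance_matrix, DistanceMatrix):
        d = distance_matrix.data
        ids = list(distance_matrix.ids)
    else:
        d = np.asarray(distance_matrix, dtype=float)
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        ids = list(ids) if ids is not None else [str(i) for i in range(len(d))]
    n = len(d)
    b = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ b @ centering
    eigvals, eigvecs = eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > 1e-10 * max(1.0, abs(eigvals[0]))
    pos_sum = eigvals[positive].sum()
    proportions = eigvals / pos_sum if pos_sum > 0 else np.zeros_like(eigvals)
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    frame = pd.DataFrame(
        coords, index=ids,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
    return PCoAResult(frame, eigvals, proportions)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    groups: list[str]

    def summary(self) -> str:
        return (f"PERMANOVA pseudo-F = {self.pseudo_f:.4f}, "
                f"p = {self.p_value:.4f} ({self.n_permutations} permutations, "
                f"{len(self.groups)} groups)")


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, n: int, g: int) -> float:
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_among = ss_total - ss_within
    denom = ss_within / (n - g)
    return np.inf if denom == 0 else (ss_among / (g - 1)) / denom


def permanova(
    distance_matrix: DistanceMatrix | np.ndarray,
    grouping: Sequence[str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Distance-based PERMANOVA with free label permutations.

    Pseudo-F follows the sums-of-squared-distances decomposition
    (among-group MS over within-group MS); the p-value is
    ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)`` so it is never 0.
    """
    d = distance_matrix.data if isinstance(distance_matrix, DistanceMatrix) \
        else np.asarray(distance_matrix, dtype=float)
    labels = np.asarray(list(grouping))
    n = len(d)
    if len(labels) != n:
        raise ValueError("grouping length must match matrix size")
    uniq = np.unique(labels)
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if n < g + 1:
        raise ValueError("need more samples than groups")
    d2 = d ** 2
    f_obs = _pseudo_f(d2, labels, n, g)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if _pseudo_f(d2, rng.permutation(labels), n, g) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(p), n_permutations, list(uniq))
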