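"""End-to-end convenience runner: scenario -> reads -> units -> profiles.

Chains the simulator and the unit-formation stages with the study defaults
(expected-error filter, pooled dereplication, OTU clustering at 97% with
97% mapping, ZOTU denoising with 100% mapping), returning everything needed
by the profile and diversity layers. Real-data workflows call the stage
functions directly on FASTQ read corpora instead.
"""

from __future__ import annotations

from dataclasses import dataclass

from .profile import PairedActivityProfile, build_all_profiles
from .seqio import Read
from .simulate import SimScenario, TrueCommunity, sample_paired_pools, simulate_community
from .units import (
    CountTable,
    TaxonUnit,
    dereplicate,
    filter_corpus,
    greedy_cluster_otus,
    map_reads_to_units,
    unoise_denoise,
)

METHOD_MIN_IDENTITY = {"OTU": 0.97, "ZOTU": 1.0}


@dataclass
class PipelineResult:
    """Everything one paired-pool run produces for one unit-formation method."""

    method: str
    units: list[TaxonUnit]
    table: CountTable
    profiles: list[PairedActivityProfile]

    def profile_for(self, sample: str) -> PairedActivityProfile:
        for p in self.profiles:
            if p.sample == sample:
                return p
        raise KeyError(sample)


def form_units(uniques, method: str, minsize: int = 8,
               identity_threshold: float = 0.97, alpha: float = 2.0):
    if method == "OTU":
        return greedy_cluster_otus(uniques, identity_threshold, minsize)
    if method == "ZOTU":
        return unoise_denoise(uniques, alpha, minsize)
    raise ValueError(f"unknown method {method!r}")


def run_corpus(
    corpus: dict[tuple[str, str], list[Read]],
    method: str = "ZOTU",
    minsize: int = 8,
    min_len: int = 230,
    max_expected_error: float = 1.0,
) -> PipelineResult:
    """Filter, dereplicate, form units, map, and profile a read corpus."""
    filtered, _ = filter_corpus(corpus, min_len=min_len,
                                max_expected_error=max_expected_error)
    uniques = dereplicate(filtered)
    units = form_units(uniques, method, minsize=minsize)
    table = map_reads_to_units(filtered, units, METHOD_MIN_IDENTITY[method])
    return PipelineResult(method, units, table, build_all_profiles(table))


def run_scenario(
    scenario: SimScenario,
    method: str = "ZOTU",
    samples: tuple[str, ...] = ("S1",),
    community: TrueCommunity | None = None,
) -> tuple[TrueCommunity, PipelineResult]:
    """Simulate a community and run the full pipeline on its reads."""
    if community is None:
        community = simulate_community(scenario)
    corpus: dict[tuple[str, str], list[Read]] = {}
    for sample in samples:
        corpus.update(sample_paired_pools(community, scenario, sample))
    return community, run_corpus(corpus, method)
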