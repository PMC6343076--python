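# riboratio

Infer cell-level microbial metabolic activity from paired 16S rDNA/rRNA
amplicon sequencing, under both classic 97% OTU clustering and
single-nucleotide (ZOTU/ESV) denoising, with a population-genome
cross-validation track and a fully ground-truthed synthetic-community
generator.

## The problem

In a microbial community, 16S rDNA amplicons report *who is there* (gene
copies track cells), while 16S rRNA amplicons report *who is making
ribosomes* (transcripts track protein-synthesis potential). For a taxonomic
unit *t* in a sample, with relative abundance `q_t^DNA` among mapped rDNA
reads and `q_t^RNA` among mapped rRNA reads, the

```
rRNA/rDNA ratio   r_t = q_t^RNA / q_t^DNA
```

is a proxy for per-cell ribosomal amplification — cell-level metabolic
activity normalized for population size. If cells of taxon *t* carry
abundance `p_t`, 16S copy number `c_t`, and activity factor `a_t`
(rRNA transcripts per gene copy), the two pools sample proportionally to
`p_t·c_t` and `p_t·c_t·a_t`, so

```
r_t = a_t / ( Σ_u p_u c_u a_u / Σ_u p_u c_u )
```

— each unit's activity over one community-wide constant. The package
estimates `r_t` per unit per sample, classifies *phantom taxa* (present in
rRNA but absent from the paired rDNA pool — undersampling or RT/PCR error
artifacts), and tests the ecological pattern that high-activity units tend
to be rare ("kill-the-winner").

Because unit formation shapes all of this, both unit-forming methods are
implemented from first principles:

- **OTUs** — greedy centroid clustering at ≥97% identity in decreasing
  abundance order, minimum centroid size 8, reads mapped back at ≥97%.
- **ZOTUs** — abundance-skew denoising: a unique sequence `u` is absorbed
  into an accepted centroid `c` at edit distance `d` when
  `size(u)/size(c) ≤ β(d) = 2^-(αd+1)` (α = 2), i.e. only if it is rare
  enough to be `c`'s error cloud; reads mapped back at 100%.

Downstream: rarefaction-averaged richness/Shannon/Faith's PD, weighted and
unweighted UniFrac, PCoA, seeded PERMANOVA; and for metagenome-derived
population genomes, relative abundance from contig coverage, relative
transcription from summed ORF TPM, their ratio (the genome-side analog of
`r_t`), and iRep replication rates from sorted log2 coverage gradients.

## Worked example

Simulate a 60-taxon community with lognormal abundances and activities,
sequence both pools at 30,000 reads with realistic RT/PCR error rates, run
the ZOTU pipeline, and compare estimated ratios against the latent truth:

```python
from scipy import stats
from riboratio import (SimScenario, run_scenario, overlap_summary,
                       ratio_distribution_stats)

scenario = SimScenario(n_taxa=60, depth_rdna=30_000, depth_rrna=30_000, seed=11)
community, result = run_scenario(scenario, method="ZOTU")
profile = result.profile_for("S1")

seq_to_taxon = dict(zip(community.references, community.taxon_ids))
activity = dict(zip(community.taxon_ids, community.activities))
rep = {u.unit_id: u.representative for u in result.units}
shared = profile.shared
rho = stats.spearmanr(
    shared["ratio"],
    [activity[seq_to_taxon[rep[u]]] for u in shared.index],
).statistic

print(f"ZOTUs formed: {len(result.units)}")
ov = overlap_summary(profile)
print(f"S1 presence classes: {ov.n_shared} shared, "
      f"{ov.n_phantom} phantom, {ov.n_dna_only} DNA-only")
st = ratio_distribution_stats([profile])
print(f"rRNA/rDNA ratios: mean {st.mean:.2f}, SD {st.sd:.2f}, "
      f"range {st.min:.2f}-{st.max:.2f}, {st.fraction_below_1:.0%} below 1")
print(f"Spearman(estimated ratio, true activity) = {rho:.3f}")
```

Output:

```
ZOTUs formed: 60
S1 presence classes: 60 shared, 0 phantom, 0 DNA-only
rRNA/rDNA ratios: mean 1.10, SD 0.97, range 0.06-4.35, 58% below 1
Spearman(estimated ratio, true activity) = 0.985
```

All 60 taxa were recovered as ZOTUs and detected in both pools (deep,
nearly error-free sequencing leaves no phantoms); the ratio distribution has
the characteristic shape of lognormal activities (most units below 1, a
long right tail); and the estimated ratios rank-order the true per-cell
activity factors almost perfectly.

A `riboratio` CLI exposes the same stages on files
(`riboratio simulate|units|profile|diversity|genome --help`).

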