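"""Call consensus genotypes from a filtered lane.

The caller is a naive-Bayes diploid model over the ten unordered genotypes:
each aligned base contributes its error probability, priors favor the
reference, and the consensus quality is the Phred-scaled probability that
the chosen genotype is wrong (quality 50 means one expected error per
100,000 calls).  Only calls at or above quality 50 are emitted.
"""

from exocap.config import RunConfig, SimulationConfig
from exocap.pipeline import run_experiment

cfg = RunConfig(
    simulation=SimulationConfig(
        chrom_lengths={"chr1": 300_000}, n_targets=80, n_pairs=20_000
    )
)
result = run_experiment(cfg, seed=7)

variants = [c for c in result.calls if c.is_variant]
print(f"confident calls:   {len(result.calls)}")
print(f"variant calls:     {len(variants)}")
print(f"heterozygous:      {sum(c.is_het for c in variants)}")
print()
print("first five variant calls (1-based positions):")
for c in variants[:5]:
    print(f"  {c.chrom}:{c.pos + 1}  {c.ref} -> {'/'.join(c.alleles)}  "
          f"quality {c.qc:.1f}  depth {c.depth}")
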