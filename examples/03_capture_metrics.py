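"""Coverage breadth, depth uniformity and insert sizes for one experiment.

Depth is counted after mate collapse, so a read pair contributes at most one
base observation per position.  Breadth is the fraction of target bases at
or above a depth threshold; the uniformity histogram partitions every target
base into exactly one depth bin.  The raw-data calculator inverts mean
depth into the whole-genome sequencing yield that a shotgun (non-captured)
design would need for the same depth.
"""

from exocap.capmetrics import raw_data_for_depth
from exocap.config import RunConfig, SimulationConfig
from exocap.pipeline import run_experiment

cfg = RunConfig(
    simulation=SimulationConfig(
        chrom_lengths={"chr1": 300_000}, n_targets=80, n_pairs=20_000
    )
)
result = run_experiment(cfg, seed=7)

cov = result.coverage
print(f"target size:     {cov.target_bases} bases")
print(f"mean depth:      {cov.mean_depth:.1f}x")
for t, frac in cov.breadth.items():
    print(f"breadth >= {t:>2}x:  {100 * frac:.2f}%")
assert result.uniformity.total == cov.target_bases  # bins partition the target

d = result.insert_dist
print(f"insert sizes:    mode {d.mode} bp, median {d.median:.0f} bp (n={d.n})")

# the shotgun-equivalent: a 3 Gb genome at this mean depth
print(f"raw shotgun data for {cov.mean_depth:.1f}x on 3 Gb: "
      f"{raw_data_for_depth(cov.mean_depth):.1f} Gb")
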