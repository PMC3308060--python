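"""Simulate a small capture lane and run the lane-level filter chain.

A synthetic 300 kb genome gets ~80 exon-like targets and a probe set; a
sequencing lane of 10,000 read pairs is drawn with realistic nuisance
processes (base errors, PCR duplicates, off-probe fragments, adapter
read-through).  The seven-step lane filter then clips adapters, keeps proper
pairs, removes duplicates, keeps pairs anchored on probes and collapses
overlapping mates.  The enrichment score — on-probe pairs over pairs
surviving deduplication — estimates how well the capture worked.
"""

from exocap.config import PipelineConfig
from exocap.capmetrics import enrichment_score
from exocap.lanefilter import run_lane
from exocap.simulate import (
    LibraryProfile, design_capture, plant_variants, simulate_genome, simulate_lane,
)

genome = simulate_genome({"chr1": 300_000}, gc_fraction=0.41, seed=1)
truth = plant_variants(genome, snv_rate=1e-3, het_fraction=0.6, seed=2)
design = design_capture(genome, n_targets=80, seed=3)
profile = LibraryProfile.gel(error_rate=0.005, duplicate_rate=0.10,
                             off_probe_fraction=0.12)
lane = simulate_lane(genome, truth, design, profile, n_pairs=10_000, seed=4)

result = run_lane(lane, design, PipelineConfig())
s = result.stats
print(f"pairs in:            {s.n_pairs_in}")
print(f"adapter-clipped:     {s.n_pairs_clipped}")
print(f"proper pairs:        {s.n_proper}")
print(f"duplicates removed:  {s.n_duplicates_removed}  (truth: {lane.n_duplicates})")
print(f"on-probe pairs:      {s.n_on_probe}")
print(f"final pairs:         {s.n_pairs_final}")
print(f"enrichment score:    {enrichment_score(s):.4f}  "
      f"(truth on-probe fraction: {1 - lane.n_off_probe / len(lane):.4f})")
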