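#!/usr/bin/env python
"""Generate the demonstration cohort: a 600 kb chromosome for four focal
diploids plus a divergence sample, with one embedded sweep, every artifact
class injected, and a high-GC tract.

Writes reference.fa, cohort.vcf (all-sites), truth.bed, genes.bed and
params.json under scratch/demo_data/ (bulky regenerable data stays out of
results/, which holds the derived tables).
"""

from pathlib import Path

from sweepscan import ArtifactRates, SweepSimParams, simulate_region

OUT = Path(__file__).resolve().parent.parent / "scratch" / "demo_data"

PARAMS = SweepSimParams(
    chrom_length=600_000,
    seed=42,
    pi_background=1e-3,
    divergence_rate=2e-3,
    het_fraction_of_divergence=0.2,
    sweep_intervals=((200_000, 260_000, 0.05),),
    artifact_rates=ArtifactRates(
        low_depth=1e-3, low_gq=1e-3, low_qual=1e-3,
        missing=1e-3, multi_allelic=1e-3,
    ),
    gc_tract=(500_000, 540_000, 0.80),
)


def main() -> None:
    sim = simulate_region(PARAMS)
    paths = sim.write_outputs(OUT)
    print(f"simulated {PARAMS.chrom_length:,} bp cohort (seed {PARAMS.seed})")
    print(f"  polymorphic sites : {sim.poly_pos.size:,}")
    print(f"  divergence sites  : {sim.div_pos.size:,} "
          f"({sim.div_is_het.mean():.0%} heterozygous)")
    print(f"  artifact sites    : {sim.artifact_pos.size:,}")
    print(f"  sweep             : 200,000-260,000 (diversity factor 0.05)")
    print(f"  high-GC tract     : 500,000-540,000 (GC 0.80)")
    for name, p in paths.items():
        print(f"  {name:10s} -> {p}")


if __name__ == "__main__":
    main()
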