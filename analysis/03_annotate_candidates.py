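#!/usr/bin/env python
"""Map significant windows onto genes and count flanking divergence.

Reads the window table from 02 and the simulated gene annotation, reports
candidate genes at empirical p < 0.10, then counts divergent vs callable
sites for the divergence sample in the 3 kb flanks of the top candidate —
the check used to judge whether a candidate region is compatible with
shared ancestry (few fixed differences) rather than deep divergence.
"""

import json
from pathlib import Path

from sweepscan import FilterConfig, flanking_divergence
from sweepscan import io as sio
from sweepscan.annotate import candidate_gene_table, read_genes_bed

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = Path(__file__).resolve().parent.parent / "scratch" / "demo_data"
ALPHA = 0.10
FLANK_BP = 1_500


def main() -> None:
    stats = sio.read_window_table(ROOT / "scan" / "windows.tsv")
    genes = read_genes_bed(DATA / "genes.bed")
    table = candidate_gene_table(stats, genes, ALPHA)
    table.to_csv(ROOT / "candidate_genes.tsv", sep="\t", index=False)
    print(f"{len(table)} candidate genes at empirical p < {ALPHA}")
    print(table.to_string(index=False))
    if table.empty:
        return

    best = table.sort_values("best_empirical_p").iloc[0]
    gene = next(g for g in genes if g.gene_id == best["gene_id"])
    manifest = json.loads((ROOT / "scan" / "manifest.json").read_text())
    ceilings = manifest["depth_ceilings"]
    cfg = FilterConfig()

    div = L = 0
    for start, end in (
        (max(0, gene.start - FLANK_BP), gene.start),
        (gene.end, gene.end + FLANK_BP),
    ):
        sites = sio.read_all_sites_vcf(DATA / "cohort.vcf")
        d, n = flanking_divergence(
            sites, "outgroup", (gene.chrom, start, end), cfg, ceilings
        )
        div += d
        L += n
    print(f"\nflanking divergence around {gene.gene_id} "
          f"({gene.chrom}:{gene.start}-{gene.end}):")
    print(f"  {div} divergent sites out of {L} flanking sites analyzed "
          f"({div / L:.2%})" if L else "  no callable flanking sites")


if __name__ == "__main__":
    main()
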