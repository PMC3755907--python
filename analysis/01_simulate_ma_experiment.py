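#!/usr/bin/env python
"""Generate the synthetic MA experiment all later steps analyse.

Builds a 1 Mb genome with an embedded homopolymer/microsatellite landscape,
evolves 16 MMR-null-like lineages for 170 generations under length-dependent
slippage (fold 4 per unit, A/T deletion bias 0.93) plus substitutions at
4.8e-9 per bp per generation, applies the long-repeat detection dropout, and
writes genome FASTA, truth repeats BED, per-lineage VCFs, span counts and
the truth event table under results/sim/.
"""

import sys
from pathlib import Path

from mapipe import io
from mapipe.simulate import (SimConfig, apply_detection_dropout,
                             generate_genome, simulate_ma_lines)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
OUT.mkdir(parents=True, exist_ok=True)

cfg = SimConfig()
print(f"generating {cfg.genome_length / 1e6:.1f} Mb genome (seed {SEED}) ...")
sequences, truth = generate_genome(cfg, seed=SEED)
io.write_fasta(sequences, OUT / "genome.fa")
io.write_bed(truth, OUT / "truth_repeats.bed")
print(f"  {len(truth)} embedded repeat loci")

calls, events = simulate_ma_lines(sequences, truth, cfg, seed=SEED)
calls, dropped = apply_detection_dropout(calls, cfg, seed=SEED)
for lineage, grp in calls.groupby("lineage_id"):
    io.write_vcf(grp, sequences, OUT / f"{lineage}.vcf")
calls[["lineage_id", "chrom", "pos", "span_reads_sample",
       "span_reads_ancestor"]].to_csv(OUT / "spans.tsv", sep="\t", index=False)
events.to_csv(OUT / "truth_events.tsv", sep="\t", index=False)
dropped.to_csv(OUT / "dropped_calls.tsv", sep="\t", index=False)

n_indel = (calls["ref"].str.len() != calls["alt"].str.len()).sum()
print(f"  {len(events)} slippage events -> {n_indel} endpoint indel calls, "
      f"{len(calls) - n_indel} substitutions across {cfg.n_lineages} lineages"
      f" ({len(dropped)} indels lost to detection dropout)")
print(f"wrote {OUT}")
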