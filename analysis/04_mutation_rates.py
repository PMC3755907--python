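#!/usr/bin/env python
"""Rates and spectrum from the classified mutations.

Computes the six-category spectrum, the per-bp substitution/indel rates
with exact Poisson CIs, and the per-repeat rate-by-length curve for A/T
homopolymers with its exponential (3-8 units) and linear (>= 9) regime
fits.  Compares every recovered parameter against the generator's truth.
Writes spectrum.tsv, length_rate_curve.tsv and rates_summary.json.
"""

import json
from pathlib import Path

import pandas as pd

import mapipe as mp
from mapipe import io
from mapipe.simulate import SimConfig

ROOT = Path(__file__).resolve().parent.parent / "results"
cfg = SimConfig()   # the generating conditions, for truth comparison

df = pd.read_csv(ROOT / "classified.tsv", sep="\t")
census = io.read_bed(ROOT / "sim" / "truth_repeats.bed")
sequences = io.read_fasta(ROOT / "sim" / "genome.fa")
G = sum(len(s) for s in sequences.values())
n_lineages = df["lineage_id"].nunique()

snv = mp.per_bp_rate(int((df["kind"] == "SNV").sum()), n_lineages,
                     cfg.generations, G)
indels = df[(df["kind"] == "indel") & df["repeat_class"].notna()]
ind_rate = mp.per_bp_rate(len(indels), n_lineages, cfg.generations, G)

ev = indels.groupby(["repeat_class", "repeat_length"]).size()
ev.index = ev.index.set_names(["motif_class", "length"])
curve = mp.per_repeat_rate_by_length(ev, census, n_lineages, cfg.generations)
mp.fit_regimes(curve, motif_class="A/T")
curve.table.to_csv(ROOT / "length_rate_curve.tsv", sep="\t", index=False)

counts = {
    "deletions_at_homopolymers": int(((indels["indel_sign"] == "deletion")
        & (indels["repeat_class"].str.len() == 3)).sum()),
    "insertions_at_homopolymers": int(((indels["indel_sign"] == "insertion")
        & (indels["repeat_class"].str.len() == 3)).sum()),
    "transitions": int((df["ts_tv"] == "transition").sum()),
    "transversions": int((df["ts_tv"] == "transversion").sum()),
    "insertions_at_microsatellites": int(((indels["indel_sign"] == "insertion")
        & (indels["repeat_class"].str.len() > 3)).sum()),
    "deletions_at_microsatellites": int(((indels["indel_sign"] == "deletion")
        & (indels["repeat_class"].str.len() > 3)).sum()),
}
spec = mp.SpectrumTable(pd.Series(counts))
spec.to_frame().to_csv(ROOT / "spectrum.tsv", sep="\t")

summary = {
    "snv_per_bp_rate": snv.rate,
    "snv_rate_ci": [snv.ci_low, snv.ci_high],
    "snv_rate_truth": cfg.snv_rate,
    "indel_per_bp_rate": ind_rate.rate,
    "fold_per_unit_recovered": curve.exp_fit["fold_per_unit"],
    "fold_per_unit_truth": cfg.slippage_fold_per_unit,
    "exp_fit_r2": curve.exp_fit["r2"],
    "spectrum_pct": spec.percentages.round(1).to_dict(),
}
(ROOT / "rates_summary.json").write_text(json.dumps(summary, indent=2))

print(f"substitution rate {snv.rate:.2e} per bp per generation "
      f"(CI {snv.ci_low:.2e}-{snv.ci_high:.2e}; truth {cfg.snv_rate:.1e})")
print(f"fold per unit (A/T, 3-8): {curve.exp_fit['fold_per_unit']:.2f} "
      f"(truth {cfg.slippage_fold_per_unit}; R^2 {curve.exp_fit['r2']:.3f})")
print(f"spectrum (%): {summary['spectrum_pct']}")
print(f"wrote spectrum.tsv, length_rate_curve.tsv, rates_summary.json")
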