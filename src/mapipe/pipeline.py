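"""End-to-end orchestration: repeats -> classify -> rates -> stats.

``run_all`` executes the full analysis from a flat key-value config and
writes a reproducible bundle (tables, stats JSON, manifest with checksums).
``fixtures_report`` recomputes every derived quantity of the packaged study
tables - spectrum percentages, per-bp rates, fold inductions and
insertion/deletion bias tests - from the raw printed counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from . import fixtures, io, rates, stats
from .classify import (classify_all, filter_span_coverage,
                       remove_shared_mutations)
from .repeats import find_repeats, nearest_neighbor_distances
from .fluctuation import FluctuationExperiment, mss_mle, p0_estimate

logger = logging.getLogger(__name__)

_CONFIG_FIELDS = {
    "fasta": str, "vcfs": list, "repeats_bed": str, "meta": str,
    "spans": str, "coding_bed": str, "timing_bed": str, "counts_tsv": str,
    "n_initial": float, "n_final": float,
    "genome_size": float, "generations": float,
    "min_hpr_len": int, "min_units": int, "min_span": int, "shared_min": int,
    "seed": int, "outdir": str,
}

_DEFAULTS = dict(genome_size=rates.DEFAULT_CALLABLE_GENOME_BP,
                 generations=rates.DEFAULT_GENERATIONS,
                 min_hpr_len=3, min_units=3, min_span=3, shared_min=3,
                 seed=0, outdir="mapipe_out")


@dataclass
class RunConfig:
    fasta: str
    vcfs: list[str]
    repeats_bed: Optional[str] = None
    meta: Optional[str] = None
    spans: Optional[str] = None
    coding_bed: Optional[str] = None
    timing_bed: Optional[str] = None
    counts_tsv: Optional[str] = None
    n_initial: float = 100.0
    n_final: float = 1e7
    genome_size: float = rates.DEFAULT_CALLABLE_GENOME_BP
    generations: float = rates.DEFAULT_GENERATIONS
    min_hpr_len: int = 3
    min_units: int = 3
    min_span: int = 3
    shared_min: int = 3
    seed: int = 0
    outdir: str = "mapipe_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(_CONFIG_FIELDS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fasta" not in raw or "vcfs" not in raw:
            raise ValueError("config must set 'fasta' and 'vcfs'")
        return cls(**raw)

    def validate(self) -> None:
        missing = []
        paths = [self.fasta, *self.vcfs, self.repeats_bed, self.meta,
                 self.spans, self.coding_bed, self.timing_bed, self.counts_tsv]
        for p in paths:
            if p is not None and not Path(p).exists():
                missing.append(p)
        if missing:
            raise FileNotFoundError(f"config references missing paths: {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mapipe")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    artifacts: list[Path] = []
    stage = "setup"
    try:
        (out / "config.yaml").write_text(yaml.safe_dump(asdict(config)))
        artifacts.append(out / "config.yaml")

        stage = "repeats"
        logger.info("stage repeats")
        sequences = io.read_fasta(config.fasta)
        if config.repeats_bed:
            census = io.read_bed(config.repeats_bed)
        else:
            census = find_repeats(sequences, config.min_hpr_len,
                                  config.min_units)
        io.write_bed(census, out / "repeats.bed")
        census.by_class_and_length().rename("count").to_csv(
            out / "repeat_census.tsv", sep="\t")
        artifacts += [out / "repeats.bed", out / "repeat_census.tsv"]

        stage = "classify"
        logger.info("stage classify")
        frames = []
        for i, vcf in enumerate(config.vcfs):
            lineage = Path(vcf).stem
            frames.append(io.read_vcf(vcf, lineage))
        calls_df = pd.concat(frames, ignore_index=True)
        if config.spans:
            spans = pd.read_csv(config.spans, sep="\t")
            calls_df = io.attach_spans(calls_df, spans)
        calls = io.calls_from_frame(calls_df)
        if len(config.vcfs) >= 2:
            calls = remove_shared_mutations(calls, config.shared_min)
        muts = classify_all(calls, census, sequences)
        if config.spans:
            muts = filter_span_coverage(muts, config.min_span)
        cls_df = pd.DataFrame([{
            "lineage_id": m.call.lineage_id, "chrom": m.call.chrom,
            "pos": m.call.pos, "ref": m.call.ref, "alt": m.call.alt,
            "kind": m.kind, "snv_class": m.snv_class, "ts_tv": m.ts_tv,
            "indel_sign": m.indel_sign,
            "repeat_class": m.repeat.motif_class if m.repeat else None,
            "repeat_start": m.repeat.start if m.repeat else None,
            "repeat_length": m.repeat.length if m.repeat else None,
            "units_changed": m.units_changed,
            "boundary_shift": m.boundary_shift} for m in muts])
        cls_df.to_csv(out / "classified.tsv", sep="\t", index=False)
        artifacts.append(out / "classified.tsv")

        stage = "rates"
        logger.info("stage rates")
        n_lineages = len(config.vcfs)
        generations = config.generations
        spec = rates.spectrum_table(muts)
        spec.to_frame().to_csv(out / "spectrum.tsv", sep="\t")
        ev = (cls_df[cls_df["kind"] == "indel"]
              .dropna(subset=["repeat_class"])
              .groupby(["repeat_class", "repeat_length"]).size())
        ev.index = ev.index.set_names(["motif_class", "length"])
        curve = rates.per_repeat_rate_by_length(ev, census, n_lineages,
                                                generations)
        rates.fit_regimes(curve, motif_class="A/T")
        curve.table.to_csv(out / "length_rate_curve.tsv", sep="\t", index=False)
        total = rates.per_bp_rate(len(muts), n_lineages, generations,
                                  config.genome_size)
        snv_rate = rates.per_bp_rate(
            int((cls_df["kind"] == "SNV").sum()), n_lineages, generations,
            config.genome_size)
        summary = {
            "n_events": len(muts),
            "per_bp_rate": total.rate,
            "per_bp_rate_ci": [total.ci_low, total.ci_high],
            "fold_induction_vs_wt": total.fold(),
            "snv_per_bp_rate": snv_rate.rate,
            "exp_fit": curve.exp_fit, "lin_fit": curve.lin_fit,
        }
        artifacts += [out / "spectrum.tsv", out / "length_rate_curve.tsv"]

        stage = "stats"
        logger.info("stage stats")
        bias_rows = []
        ind = cls_df[(cls_df["kind"] == "indel")
                     & cls_df["repeat_class"].notna()]
        for cls, grp in ind.groupby("repeat_class"):
            b = stats.indel_bias_test(
                int((grp["indel_sign"] == "insertion").sum()),
                int((grp["indel_sign"] == "deletion").sum()), cls)
            bias_rows.append({"motif_class": cls, "n_ins": b.n_ins,
                              "n_del": b.n_del,
                              "deletion_fraction": b.deletion_fraction,
                              "chi2": b.chi2, "p": b.p, "low_n": b.low_n})
        pd.DataFrame(bias_rows).to_csv(out / "bias.tsv", sep="\t", index=False)
        artifacts.append(out / "bias.tsv")

        nn = nearest_neighbor_distances(census)
        mutated_keys = set(zip(ind["chrom"], ind["repeat_start"].astype(int)))
        nn["mutated"] = [
            (c, s) in mutated_keys for c, s in zip(nn["chrom"], nn["start"])]
        d_all = nn["nn_distance"].to_numpy()
        d_mut = nn.loc[nn["mutated"], "nn_distance"].to_numpy()
        prox = None
        if (nn["mutated"].sum() >= 2) and len(nn) >= 2:
            pr = stats.proximity_ks(d_mut, d_all)
            prox = {"ks_D": pr.ks_D, "p": pr.p,
                    "mutated_within_3bp": stats.cumulative_within(d_mut, 3),
                    "all_within_3bp": stats.cumulative_within(d_all, 3)}
            pd.concat([pr.ecdf_all.assign(which="all"),
                       pr.ecdf_mutated.assign(which="mutated")]) \
              .to_csv(out / "proximity_ecdf.tsv", sep="\t", index=False)
            artifacts.append(out / "proximity_ecdf.tsv")
        summary["proximity"] = prox

        if config.counts_tsv:
            stage = "fluctuation"
            logger.info("stage fluctuation")
            counts = pd.read_csv(config.counts_tsv, sep="\t")["mutants"]
            exp = FluctuationExperiment(tuple(int(c) for c in counts),
                                        n_final=config.n_final,
                                        n_initial=config.n_initial)
            res = {}
            try:
                p0 = p0_estimate(exp)
                res["P0"] = asdict(p0)
            except ValueError as e:
                res["P0"] = {"error": str(e)}
            res["MSS-MLE"] = asdict(mss_mle(exp))
            summary["fluctuation"] = res

        (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     default=float))
        artifacts.append(out / "summary.json")

        stage = "manifest"
        artifacts.append(log_path)
        manifest = {
            "mapipe_version": __version__,
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "seed": config.seed,
            "inputs": {str(p): _sha256(Path(p))
                       for p in [config.fasta, *config.vcfs] if p},
            "artifacts": {p.name: _sha256(p) for p in artifacts
                          if p.exists() and p != log_path},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as err:
        (out / "FAILED").write_text(f"stage {stage}: {err}\n")
        raise StageError(stage, err) from err
    finally:
        root.removeHandler(handler)
        handler.close()


def fixtures_report() -> dict:
    """Recompute all derived quantities from the packaged study tables.

    Everything is computed from raw integer counts at run time: spectrum
    percentages (exact integer arithmetic over the six categories), per-bp
    rates with the callable genome size, fold inductions against the
    wild-type reference rate, and chi-square insertion/deletion bias tests
    per motif class.
    """
    spec = rates.SpectrumTable(fixtures.spectrum_counts())
    t2 = fixtures.lineage_counts()
    null = t2[t2["functional_class"] == "null_like"]
    n_null = len(null)
    sbs_total = int(null["sbs"].sum())
    indel_total = int(null["indels"].sum())
    events_total = sbs_total + indel_total

    per_lineage = {}
    for _, r in t2.iterrows():
        est = rates.per_bp_rate(int(r["sbs"] + r["indels"]), 1)
        per_lineage[r["genotype"]] = {
            "events": int(r["sbs"] + r["indels"]),
            "rate": est.rate,
            "fold": est.fold(),
        }
    null_rates = [per_lineage[g]["rate"] for g in null["genotype"]]
    sbs_rate = rates.per_bp_rate(sbs_total, n_null)
    indel_rate = rates.per_bp_rate(indel_total, n_null)

    t4 = fixtures.indel_bias_counts()
    bias = {}
    for _, r in t4.iterrows():
        b = stats.indel_bias_test(int(r["insertions"]), int(r["deletions"]),
                                  r["motif_class"])
        bias[r["motif_class"]] = {
            "n": b.n, "insertion_fraction": b.insertion_fraction,
            "deletion_fraction": b.deletion_fraction,
            "chi2": b.chi2, "p": b.p, "low_n": b.low_n}

    return {
        "spectrum": {
            "counts": spec.counts.to_dict(),
            "total": spec.total,
            "percentages": spec.percentages.round(1).to_dict(),
            "subtotals": spec.subtotals.to_dict(),
            "subtotal_percentages": spec.subtotal_percentages.round(1).to_dict(),
        },
        "lineages": {
            "n_null_like": n_null,
            "sbs_total_null_like": sbs_total,
            "indel_total_null_like": indel_total,
            "events_total_null_like": events_total,
            "per_lineage": per_lineage,
            "mean_null_rate": sum(null_rates) / n_null,
            "sbs_per_bp_rate": sbs_rate.rate,
            "indel_per_bp_rate": indel_rate.rate,
        },
        "bias": bias,
    }
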