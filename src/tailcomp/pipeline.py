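"""Pipeline orchestration, configuration, alignment-flag utilities and
sample-metadata IO.

``run_pipeline`` chains the stages end to end: simulate one or more DRS
samples, segment every read and tag its quality, keep the usable
(PASS/SUFFCLIP) reads, train the residue classifier, detect and classify
non-A residues, summarise composition / positional / concordance
statistics, and finally run the count-based DE analogue with the
terminal-U overlay.  Every stochastic stage takes an explicit seed derived
from the config, so a rerun with the same config reproduces the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detect, expression, segment, squiggle, tailstats

logger = logging.getLogger("tailcomp")

# standard alignment-record flag bits (SAM convention)
ALIGNMENT_FLAGS = {
    "paired": 1,
    "proper_pair": 2,
    "unmapped": 4,
    "mate_unmapped": 8,
    "reverse_strand": 16,
    "mate_reverse_strand": 32,
    "first_in_pair": 64,
    "second_in_pair": 128,
    "secondary": 256,
    "qc_fail": 512,
    "duplicate": 1024,
    "supplementary": 2048,
}

METADATA_COLUMNS = ["sample_name", "replicate", "species", "organ", "platform",
                    "project", "accession", "seq_data_link", "seq_source",
                    "nonA_data", "diffexp_data"]


class FormatError(ValueError):
    """Malformed metadata or config input."""


def alignment_filter_mask(exclude) -> int:
    """Bitwise union of named alignment flags (e.g. for ``samtools view -F``).

    ``{reverse_strand, secondary, supplementary}`` gives 2320, the mask used
    to restrict DRS alignments to primary forward-strand records.
    """
    mask = 0
    for name in exclude:
        if name not in ALIGNMENT_FLAGS:
            raise KeyError(f"unknown alignment flag name: {name!r}")
        mask |= ALIGNMENT_FLAGS[name]
    return mask


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Complete, serialisable configuration of a pipeline run."""

    seed: int = 0
    #: demo samples are denser in decorated reads than the benchmark
    #: default so the terminal-enrichment and overlay stages have enough
    #: residue calls per transcript to work with
    samples: list[squiggle.SampleConfig] = field(
        default_factory=lambda: [
            squiggle.SampleConfig(name="rep1", n_reads=400,
                                  decorated_fraction=0.3, n_transcripts=12),
            squiggle.SampleConfig(name="rep2", n_reads=400,
                                  decorated_fraction=0.3, n_transcripts=12),
        ])
    model_k: int = 5
    model_seed: int = 7
    separation: float = squiggle.DEFAULT_SEPARATION
    segmentation: segment.SegmentationParams = field(
        default_factory=segment.SegmentationParams)
    detection: detect.DetectionParams = field(default_factory=detect.DetectionParams)
    n_train_per_class: int = 120
    n_perm: int = 999
    terminal_alpha: float = 0.05
    min_calls: int = 10
    de: expression.DEParams = field(default_factory=expression.DEParams)
    de_n_per_condition: int = 3
    de_dispersion: float = 0.1
    de_terminal_lfc: float = -1.5
    write_signals: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        d["samples"] = [squiggle.SampleConfig(**_tupled(s, ("tail_length_range",
                                                            "transcript_length_range")))
                        for s in d.get("samples", [])]
        if "segmentation" in d:
            d["segmentation"] = segment.SegmentationParams(**d["segmentation"])
        if "detection" in d:
            d["detection"] = detect.DetectionParams(**d["detection"])
        if "de" in d:
            d["de"] = expression.DEParams(**d["de"])
        return PipelineConfig(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_listed(self.to_dict()), fh, sort_keys=False)

    @staticmethod
    def load(path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh))


def _tupled(d: dict, keys) -> dict:
    d = dict(d)
    for k in keys:
        if k in d and d[k] is not None:
            d[k] = tuple(d[k])
    return d


def _listed(obj):
    """YAML-friendly copy: tuples become lists recursively."""
    if isinstance(obj, dict):
        return {k: _listed(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listed(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# Sample metadata table (Data-Record dialect)
# ---------------------------------------------------------------------------

def read_metadata_table(path=None) -> pd.DataFrame:
    """Read the 11-column sample metadata table.

    With no path, the packaged transcription of the study's deposited-sample
    table is read.  nonA_data / diffexp_data must be 'Y' or 'n'.
    """
    if path is None:
        with resources.files("tailcomp.data").joinpath(
                "sample_metadata.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata table missing column(s): {', '.join(missing)}")
    for col in ("nonA_data", "diffexp_data"):
        bad = set(df[col]) - {"Y", "n"}
        if bad:
            raise FormatError(f"illegal {col} value(s): {sorted(bad)} (allowed: Y, n)")
    return df


def filter_metadata(df: pd.DataFrame, organ: str | None = None,
                    platform: str | None = None) -> pd.DataFrame:
    out = df
    if organ is not None:
        out = out[out["organ"] == organ]
    if platform is not None:
        out = out[out["platform"] == platform]
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, workdir) -> dict:
    """Execute simulate -> segment -> filter -> detect -> stats -> expression.

    Writes per-sample class_data/residue_data TSVs, composition, QC-tag,
    terminal-test and concordance tables, DE results with the terminal-U
    overlay, and a manifest with seeds and per-stage row counts.  Returns
    the manifest dict.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    rng = np.random.default_rng(config.seed)

    def _seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    stage = "simulate"
    try:
        model = squiggle.build_pore_model(config.model_k, seed=config.model_seed,
                                          separation=config.separation)
        samples = {}
        for sc in config.samples:
            s = _seed()
            reads, truth_reads, truth_residues, transcripts = \
                squiggle.simulate_sample(sc, model, seed=s, return_transcripts=True)
            samples[sc.name] = {
                "config": sc, "seed": s, "reads": reads,
                "truth_reads": truth_reads, "truth_residues": truth_residues,
                "transcripts": transcripts,
            }
            logger.info("stage=%s sample=%s seed=%d reads=%d", stage, sc.name,
                        s, len(reads))
        manifest["stages"][stage] = {
            name: {"seed": d["seed"], "n_reads": len(d["reads"])}
            for name, d in samples.items()}

        stage = "segment"
        for name, d in samples.items():
            segs = []
            for read in d["reads"]:
                segs.append(segment.segment_signal(
                    read.signal, model, config.segmentation,
                    read_id=read.read_id,
                    transcript_nt=read.transcript_length_nt,
                    transcript_seq=d["transcripts"].get(read.transcript_id),
                    contig=read.transcript_id))
            d["segmentations"] = segs
            segment.write_polya_tsv(segs, workdir / f"{name}_polya.tsv")
        tag_summary = tailstats.tag_frequency_summary(
            {name: d["segmentations"] for name, d in samples.items()})
        tag_summary.to_csv(workdir / "tag_frequencies.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            name: {"n_segmented": len(d["segmentations"])}
            for name, d in samples.items()}

        stage = "filter"
        for d in samples.values():
            d["usable"] = segment.filter_usable(d["segmentations"])
        manifest["stages"][stage] = {
            name: {"n_usable": len(d["usable"])} for name, d in samples.items()}

        stage = "train_classifier"
        train_seed = _seed()
        noise = config.samples[0].noise_sd if config.samples else 2.0
        windows = detect.make_training_windows(
            model, n_per_class=config.n_train_per_class, noise_sd=noise,
            seed=train_seed, params=config.detection)
        classifier = detect.train_classifier(windows, seed=train_seed,
                                             params=config.detection,
                                             a_level=model.a_level)
        manifest["stages"][stage] = {
            "seed": train_seed, "n_windows": len(windows),
            "heldout_macro_recall": classifier.heldout_macro_recall}

        stage = "detect"
        for name, d in samples.items():
            signals = {r.read_id: r.signal for r in d["reads"]}
            class_data, residue_data = detect.run_detection(
                signals, d["segmentations"], classifier, model, config.detection)
            d["class_data"] = class_data
            d["residue_data"] = residue_data
            class_data.to_csv(workdir / f"{name}_class_data.tsv", sep="\t", index=False)
            residue_data.to_csv(workdir / f"{name}_residue_data.tsv", sep="\t",
                                index=False)
        manifest["stages"][stage] = {
            name: {"n_class_rows": len(d["class_data"]),
                   "n_residue_rows": len(d["residue_data"])}
            for name, d in samples.items()}

        stage = "stats"
        comps = []
        per_tx = {}
        terminal_rows = []
        for name, d in samples.items():
            read_tx = {r.read_id: r.transcript_id for r in d["reads"]}
            comps.append(tailstats.composition_frequencies(
                d["class_data"], d["residue_data"], sample_name=name))
            per_tx[name] = tailstats.per_transcript_summary(d["class_data"], read_tx)
            for tx_id in sorted({r.transcript_id for r in d["reads"]}):
                profile = tailstats.positional_profile(d["residue_data"], tx_id, read_tx)
                stat, p = tailstats.terminal_enrichment_test(
                    profile, n_perm=config.n_perm, seed=_seed(),
                    min_calls=config.min_calls)
                terminal_rows.append({
                    "sample_name": name, "transcript_id": tx_id,
                    "n_calls": len(profile.points),
                    "median_relative_position": stat, "p_value": p})
        pd.DataFrame([dataclasses.asdict(c) for c in comps]).to_csv(
            workdir / "composition.tsv", sep="\t", index=False)
        terminal_df = pd.DataFrame(terminal_rows)
        terminal_df.to_csv(workdir / "terminal_tests.tsv", sep="\t", index=False)
        if len(samples) >= 2:
            for metric, fname in (("counts", "concordance_counts.tsv"),
                                  ("mean_polya_length", "concordance_tails.tsv")):
                mat = tailstats.concordance_matrix(per_tx, metric=metric)
                mat.to_csv(workdir / fname, sep="\t")
        manifest["stages"][stage] = {"n_terminal_tests": len(terminal_df)}

        stage = "expression"
        first = next(iter(samples))
        sub = terminal_df[terminal_df["sample_name"] == first]
        flagged = sorted(sub.loc[sub["p_value"] < config.terminal_alpha,
                                 "transcript_id"])
        tx_ids = sorted({r.transcript_id for r in samples[first]["reads"]})
        de_seed = _seed()
        # align simulated gene ids with transcript ids; terminal-U transcripts
        # receive the configured (negative) true fold change
        de_gene_map = {f"gene_{tx_ids.index(g):04d}": config.de_terminal_lfc
                       for g in flagged}
        counts, conditions = expression.simulate_counts(
            n_genes=len(tx_ids), n_per_condition=config.de_n_per_condition,
            dispersion=config.de_dispersion, seed=de_seed,
            de_genes=de_gene_map or None)
        counts.index = tx_ids
        results = expression.nb_wald_test(counts, conditions, config.de)
        annotated, enrichment = expression.terminal_u_overlay(
            results, flagged, config.de)
        annotated.to_csv(workdir / "de_results.tsv", sep="\t",
                         index_label="gene_id")
        with open(workdir / "enrichment.tsv", "w") as fh:
            fh.write("odds_ratio\tp_value\tn_flagged\n")
            fh.write(f"{enrichment['odds_ratio']}\t{enrichment['p_value']}\t"
                     f"{len(flagged)}\n")
        manifest["stages"][stage] = {
            "seed": de_seed, "n_genes": len(results),
            "n_terminal_u_flagged": len(flagged),
            "fisher_odds_ratio": enrichment["odds_ratio"],
            "fisher_p": enrichment["p_value"]}

        if config.write_signals:
            stage = "write_signals"
            for name, d in samples.items():
                squiggle.write_sample(workdir / name, d["reads"],
                                      d["truth_reads"], d["truth_residues"],
                                      transcripts=d["transcripts"])
    except Exception as exc:  # partial outputs are retained in workdir
        raise StageError(stage, exc) from exc

    with open(workdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
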