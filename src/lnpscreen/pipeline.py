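"""Run configuration and stage orchestration: simulate -> quantify -> enrich -> sar.

A run is described by a single YAML key-value config.  Every stage writes
TSV outputs prefixed with a provenance comment line carrying the package
version and the config hash, so identical config + seed reproduce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

import lnpscreen
from lnpscreen import enrich as _enrich
from lnpscreen import lipids as _lipids
from lnpscreen import quantify as _quantify
from lnpscreen import simulate as _simulate
from lnpscreen.simulate import ORGANS, BarcodeWhitelist, BiodistributionModel, ReadLayout

__all__ = ["RunConfig", "run_simulate", "run_quantify", "run_enrich", "run_sar", "run_all"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """All knobs for one screening run; round-trips through YAML unchanged."""

    # global
    seed: int = 0
    out_dir: str = "lnpscreen_out"
    # paths (optional; simulate fills them in)
    whitelist: str | None = None
    sample_sheet: str | None = None
    fastq_dir: str | None = None
    rlu_table: str | None = None
    core_registry: str | None = None
    tail_registry: str | None = None
    # read layout
    prefix_seq: str = ReadLayout.prefix_seq
    suffix_seq: str = ReadLayout.suffix_seq
    barcode_len: int = 8
    umi_len: int = 8
    # simulator
    n_barcodes: int = 96
    n_mice: int = 5
    organs: tuple = ORGANS
    pool_replicates: int = 1
    naked_reference: bool = True
    min_dist: int = 3
    molecules_per_organ: int = 20_000
    mouse_sd: float = 0.3
    pcr_cycles: int = 2
    pcr_efficiency: float = 0.5
    seq_error_rate: float = 1e-3
    planted_n: int = 0
    planted_organ: str = "lung"
    planted_fold: float = 8.0
    # quantification
    anchor_max_mm: int = 2
    barcode_max_mm: int = 1
    collapse_method: str = "directional"
    # enrichment
    pseudocount: float = 0.5
    comparison: str = "one_vs_rest"
    fc_threshold: float = 1.0
    q_threshold: float = 0.05
    bh_scope: str = "organ"
    # sar
    rlu_threshold: float = 100.0
    rlu_agg: str = "mean"
    hit_rate_denominator: str = "library"

    def layout(self) -> ReadLayout:
        return ReadLayout(
            prefix_seq=self.prefix_seq,
            suffix_seq=self.suffix_seq,
            barcode_len=self.barcode_len,
            umi_len=self.umi_len,
        )

    def validate(self) -> None:
        errors = []
        if self.n_mice < 1:
            errors.append("n_mice must be >= 1")
        if self.n_barcodes < 1:
            errors.append("n_barcodes must be >= 1")
        if not self.organs:
            errors.append("organ list must be non-empty")
        if self.planted_n > self.n_barcodes:
            errors.append("planted_n cannot exceed n_barcodes")
        if self.planted_n and self.planted_organ not in self.organs:
            errors.append(f"planted_organ {self.planted_organ!r} not in organs")
        if self.collapse_method not in ("directional", "unique"):
            errors.append(f"unknown collapse_method {self.collapse_method!r}")
        if self.comparison not in ("one_vs_rest", "vs_pool_replicates"):
            errors.append(f"unknown comparison {self.comparison!r}")
        for name in ("whitelist", "sample_sheet", "rlu_table", "core_registry", "tail_registry"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                errors.append(f"{name} file not found: {path}")
        if errors:
            raise ConfigError("invalid config: " + "; ".join(errors))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["organs"] = list(self.organs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "organs" in kwargs:
            kwargs["organs"] = tuple(kwargs["organs"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    #: path-like fields excluded from the config hash so that the same
    #: scientific parameters hash identically wherever the run lives
    _PATH_FIELDS = (
        "out_dir", "whitelist", "sample_sheet", "fastq_dir",
        "rlu_table", "core_registry", "tail_registry",
    )

    def hash(self) -> str:
        d = {k: v for k, v in self.to_dict().items() if k not in self._PATH_FIELDS}
        canonical = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return f"# lnpscreen {lnpscreen.__version__} config={config.hash()}"


def _write_tsv(df: pd.DataFrame, path, config: RunConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def _log(verbosity: int, level: int, msg: str) -> None:
    if verbosity >= level:
        print(msg, file=sys.stderr)


def _planted_ids(config: RunConfig, whitelist: BarcodeWhitelist) -> list[str]:
    """Deterministic choice of the planted-tropism barcodes."""
    ids = [
        b
        for b, lnp in zip(whitelist.barcode_ids, whitelist.entries["lnp_name"])
        if lnp != _simulate.NAKED_LNP
    ]
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 3)))
    chosen = rng.choice(len(ids), size=config.planted_n, replace=False)
    return [ids[i] for i in sorted(chosen)]


def _build_model(config: RunConfig, whitelist: BarcodeWhitelist) -> BiodistributionModel:
    model = BiodistributionModel.neutral(
        whitelist,
        organs=config.organs,
        mouse_sd=config.mouse_sd,
        molecules_per_organ=config.molecules_per_organ,
        pcr_cycles=config.pcr_cycles,
        pcr_efficiency=config.pcr_efficiency,
        seq_error_rate=config.seq_error_rate,
        seed=config.seed,
    )
    if config.planted_n:
        model = model.with_planted_tropism(
            _planted_ids(config, whitelist), config.planted_organ, config.planted_fold
        )
    return model


def run_simulate(config: RunConfig, verbosity: int = 1) -> dict:
    """Simulate a full screen: whitelist, truth tables, sample sheet, FASTQ."""
    config.validate()
    out = config.out_dir
    fastq_dir = os.path.join(out, "fastq")
    os.makedirs(fastq_dir, exist_ok=True)
    whitelist = _simulate.design_whitelist(
        config.n_barcodes,
        barcode_len=config.barcode_len,
        min_dist=config.min_dist,
        seed=config.seed,
        include_naked_control=config.naked_reference,
    )
    model = _build_model(config, whitelist)
    truth = _simulate.simulate_screen(
        model,
        whitelist,
        n_mice=config.n_mice,
        organs=config.organs,
        pool_replicates=config.pool_replicates,
        naked_reference=config.naked_reference,
    )
    manifest = _simulate.simulate_reads(truth, config.layout(), whitelist, model, fastq_dir)

    whitelist_path = os.path.join(out, "whitelist.tsv")
    sheet_path = os.path.join(out, "sample_sheet.tsv")
    whitelist.to_tsv(whitelist_path)
    _write_tsv(truth.samples, sheet_path, config)
    _write_tsv(truth.counts.rename_axis("barcode_id").reset_index(),
               os.path.join(out, "truth_counts.tsv"), config)
    _write_tsv(truth.tropism.rename_axis("barcode_id").reset_index(),
               os.path.join(out, "truth_tropism.tsv"), config)
    config.whitelist = whitelist_path
    config.sample_sheet = sheet_path
    config.fastq_dir = fastq_dir
    config.to_yaml(os.path.join(out, "run_config.yaml"))
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(
            {
                "config_hash": config.hash(),
                "version": lnpscreen.__version__,
                "samples": manifest.to_dict("records"),
                "layout": config.layout().to_dict(),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    _log(verbosity, 1, f"simulate wrote {len(manifest)} FASTQ files to {fastq_dir}")
    return {"whitelist": whitelist, "model": model, "truth": truth, "manifest": manifest}


def _load_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def run_quantify(config: RunConfig, verbosity: int = 1) -> _quantify.CountTable:
    """FASTQ -> deduplicated count table, written to counts.tsv / qc.tsv."""
    config.validate()
    if config.whitelist is None or config.sample_sheet is None or config.fastq_dir is None:
        raise ConfigError("quantify needs whitelist, sample_sheet and fastq_dir")
    whitelist = BarcodeWhitelist.from_tsv(config.whitelist)
    sheet = _load_sample_sheet(config.sample_sheet)
    table = _quantify.build_count_table(
        config.fastq_dir,
        sheet,
        whitelist,
        config.layout(),
        anchor_max_mm=config.anchor_max_mm,
        max_mm=config.barcode_max_mm,
        method=config.collapse_method,
        log=(lambda msg: _log(verbosity, 2, msg)),
    )
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    _write_tsv(table.counts.rename_axis("barcode_id").reset_index(),
               os.path.join(out, "counts.tsv"), config)
    _write_tsv(table.qc, os.path.join(out, "qc.tsv"), config)
    _log(verbosity, 1, f"quantify processed {len(sheet)} samples")
    return table


def run_enrich(config: RunConfig, table: _quantify.CountTable | None = None,
               verbosity: int = 1) -> dict:
    """Count table -> enrichment records, candidates, heatmap and volcano tables."""
    config.validate()
    out = config.out_dir
    if table is None:
        sheet = _load_sample_sheet(config.sample_sheet)
        table = _quantify.CountTable.from_tsv(os.path.join(out, "counts.tsv"), sheet)
    normalized = _enrich.build_normalized_table(table, pseudocount=config.pseudocount)
    records = _enrich.enrichment_analysis(
        normalized,
        comparison=config.comparison,
        fc_threshold=config.fc_threshold,
        q_threshold=config.q_threshold,
        bh_scope=config.bh_scope,
    )
    candidates = _enrich.classify_tropism(
        records,
        fc_threshold=config.fc_threshold,
        q_threshold=config.q_threshold,
    )
    heat = _enrich.heatmap_matrix(normalized)
    heat_scaled = _enrich.heatmap_matrix(normalized, row_scale=True)

    _write_tsv(records, os.path.join(out, "enrichment.tsv"), config)
    _write_tsv(pd.DataFrame({"barcode_id": candidates}),
               os.path.join(out, "candidates.tsv"), config)
    _write_tsv(heat.rename_axis("barcode_id").reset_index(),
               os.path.join(out, "heatmap.tsv"), config)
    _write_tsv(heat_scaled.rename_axis("barcode_id").reset_index(),
               os.path.join(out, "heatmap_rowscaled.tsv"), config)
    volcano = records.rename(columns={"log2fc": "x_log2fc"}).assign(
        y_neglog10q=-np.log10(records["q_value"].clip(lower=1e-300))
    )
    _write_tsv(volcano, os.path.join(out, "volcano.tsv"), config)
    _log(verbosity, 1, f"enrich called {len(candidates)} candidate barcode(s)")
    return {"normalized": normalized, "records": records, "candidates": candidates,
            "heatmap": heat}


def run_sar(config: RunConfig, verbosity: int = 1) -> dict:
    """RLU table -> hit flags and per-feature hit-rate tables."""
    config.validate()
    if config.rlu_table is None:
        raise ConfigError("sar needs an rlu_table path")
    cores = (_lipids.load_core_registry(config.core_registry)
             if config.core_registry else _lipids.default_core_registry())
    tails = (_lipids.load_tail_registry(config.tail_registry)
             if config.tail_registry else _lipids.default_tail_registry())
    library = _lipids.enumerate_library(cores, tails)
    rlu = _lipids.load_rlu_table(config.rlu_table)
    hits = _lipids.classify_hits(rlu, threshold=config.rlu_threshold, agg=config.rlu_agg)
    unknown = [n for n in hits.index if n not in {d.name for d in library}]
    if unknown:
        raise ConfigError(f"RLU lipids not in library: {unknown[:5]}")
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    _write_tsv(hits.rename("hit").rename_axis("lipid_name").reset_index(),
               os.path.join(out, "sar_hits.tsv"), config)
    rates = {}
    for feature in _lipids.FEATURES:
        rate = _lipids.hit_rate_by_feature(
            hits, library, feature, denominator=config.hit_rate_denominator
        )
        rates[feature] = rate
        _write_tsv(rate, os.path.join(out, f"sar_hit_rate_{feature}.tsv"), config)
    _log(verbosity, 1, f"sar flagged {int(hits.sum())} hits / {len(library)} lipids")
    return {"library": library, "hits": hits, "rates": rates}


def run_all(config: RunConfig, force: bool = False, verbosity: int = 1) -> dict:
    """simulate (unless FASTQ provided) -> quantify -> enrich -> sar (if RLU given)."""
    config.validate()
    sentinel = os.path.join(config.out_dir, "enrichment.tsv")
    if os.path.exists(sentinel) and not force:
        raise ConfigError(
            f"output {sentinel} exists; pass force=True (--force) to overwrite"
        )
    results: dict = {}
    stage = "simulate"
    try:
        if config.fastq_dir is None:
            results["simulate"] = run_simulate(config, verbosity=verbosity)
        stage = "quantify"
        table = run_quantify(config, verbosity=verbosity)
        results["counts"] = table
        stage = "enrich"
        results["enrich"] = run_enrich(config, table=table, verbosity=verbosity)
        if config.rlu_table is not None:
            stage = "sar"
            results["sar"] = run_sar(config, verbosity=verbosity)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results
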