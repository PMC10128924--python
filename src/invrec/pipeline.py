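"""Configuration and the simulate → panel → call → stats pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as invio
from .caller import (
    assign_parental_origin,
    call_events,
    detect_nondisjunction,
    find_jackpots,
    restrict_to_selected_interval,
)
from .panel import MarkerPanel, build_diagnostic_panel, mask_low_density, snv_density_windows
from .sim import (
    DEFAULT_MARKERS,
    InversionCrossModel,
    SelectionScheme,
    simulate_cross,
    synthetic_panel,
)
from .stats import bin_and_normalize, format_p, map_length_cM, spearman_distance_corr

log = logging.getLogger(__name__)

__version__ = "0.1.0"


class ConfigError(ValueError):
    """Invalid pipeline configuration; raised before any stage runs."""


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; validates before execution."""

    chrom: str = "chrX"
    chrom_length: int = 23_542_271
    seed: int = 1
    out_dir: str = "invrec_out"
    # panel: either two parental VCFs or the synthetic generator
    p1_vcf: str | None = None
    p2_vcf: str | None = None
    mean_spacing: float = 367.0
    low_density_region: tuple[int, int] | None = (1, 4_897_260)
    low_density_spacing: float = 81_540.0
    density_window: int = 50_000
    density_step: int = 25_000
    min_sites_per_window: int = 10
    # simulation
    model: InversionCrossModel = field(default_factory=InversionCrossModel)
    scheme: SelectionScheme = field(default_factory=SelectionScheme)
    n_offspring: int = 100
    error_rate: float = 0.0
    missing_rate: float = 0.0
    jackpot_clone_sizes: tuple[int, ...] = ()
    # caller
    min_support_co: int = 2
    max_ncogc_span: int = 10_000
    y_cov_threshold: float = 0.1
    # stats
    stats_window: int = 150_000
    analysis_interval: tuple[int, int] | None = None  # default: proximal bp -> f

    def validate(self) -> None:
        if self.chrom_length <= 0:
            raise ConfigError("chrom_length must be positive")
        if self.model.chrom_length != self.chrom_length:
            raise ConfigError("model.chrom_length disagrees with chrom_length")
        if self.model.breakpoint_proximal >= self.chrom_length:
            raise ConfigError("proximal breakpoint beyond chromosome end")
        for name, pos in self.scheme.markers.items():
            if not (1 <= pos <= self.chrom_length):
                raise ConfigError(f"marker {name} outside chromosome")
        if self.analysis_interval is not None:
            a, b = self.analysis_interval
            if not (0 <= a < b <= self.chrom_length):
                raise ConfigError("bad analysis_interval")
        if self.n_offspring < 1:
            raise ConfigError("n_offspring must be >= 1")
        if not (0 <= self.error_rate <= 1 and 0 <= self.missing_rate <= 1):
            raise ConfigError("rates must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            if "model" in raw and isinstance(raw["model"], dict):
                raw["model"] = InversionCrossModel(**raw["model"])
            if "scheme" in raw and isinstance(raw["scheme"], dict):
                s = dict(raw["scheme"])
                if "select" in s:
                    s["select"] = tuple(s["select"])
                raw["scheme"] = SelectionScheme(**s)
            for key in ("low_density_region", "analysis_interval", "jackpot_clone_sizes"):
                if raw.get(key) is not None:
                    raw[key] = tuple(raw[key])
            cfg = cls(**raw)
        except (TypeError, ValueError) as e:
            raise ConfigError(str(e)) from None
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model"] = dataclasses.asdict(self.model)
        d["scheme"] = dataclasses.asdict(self.scheme)
        return d


@dataclass
class RunManifest:
    """Provenance of one pipeline run: config hash, seeds, file checksums."""

    config_sha256: str
    version: str
    seed: int
    stage_seeds: dict[str, int]
    outputs: dict[str, str]  # relative path -> sha256
    started: float = 0.0
    finished: float = 0.0
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def stage_seeds(master: int, names=("panel", "simulate", "call", "stats")) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2**31) derived from one master seed."""
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute simulate → panel → call → stats; write outputs + manifest.

    Raises :class:`ConfigError` before touching disk if the config is
    invalid; on a stage failure, partial outputs are retained and the
    manifest records the failed stage before the exception propagates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    cfg_dict = config.to_dict()
    cfg_dict.pop("out_dir", None)  # where outputs land is not part of what was run
    manifest = RunManifest(
        config_sha256=hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        version=__version__,
        seed=config.seed,
        stage_seeds=seeds,
        outputs={},
        started=time.time(),
    )

    def record(path: Path) -> None:
        manifest.outputs[path.name] = _sha256_file(path)

    stage = "panel"
    try:
        # ---- panel ----
        if config.p1_vcf and config.p2_vcf:
            p1 = invio.read_vcf_calls(config.p1_vcf, chrom=config.chrom)
            p2 = invio.read_vcf_calls(config.p2_vcf, chrom=config.chrom)
            panel = build_diagnostic_panel(p1, p2, config.chrom_length)
        else:
            panel = synthetic_panel(
                chrom=config.chrom,
                chrom_length=config.chrom_length,
                mean_spacing=config.mean_spacing,
                low_density_region=config.low_density_region,
                low_density_spacing=config.low_density_spacing,
                seed=seeds["panel"],
            )
        profile = snv_density_windows(panel, config.density_window, config.density_step)
        panel = mask_low_density(panel, profile, config.min_sites_per_window)
        invio.write_panel_tsv(panel, out / "panel.tsv")
        invio.write_density_bedgraph(profile, out / "snv_density.tsv")
        record(out / "panel.tsv")
        record(out / "snv_density.tsv")
        log.info("panel: %d sites (%d unmasked)", panel.n_sites, panel.n_unmasked)

        # ---- simulate ----
        stage = "simulate"
        offspring = simulate_cross(
            config.model,
            panel,
            config.scheme,
            config.n_offspring,
            error_rate=config.error_rate,
            missing_rate=config.missing_rate,
            seed=seeds["simulate"],
            jackpot_clone_sizes=config.jackpot_clone_sizes,
        )
        invio.write_genotype_matrix(panel, [o.observation for o in offspring], out / "genotypes.tsv")
        invio.write_coverage_tsv(
            [(o.offspring_id, o.observation.y_coverage, o.observation.selection_class) for o in offspring],
            out / "coverage.tsv",
        )
        with open(out / "truth.tsv", "w") as fh:
            fh.write("offspring\tndj\tjackpot\tco_positions\ttracts\n")
            for o in offspring:
                if o.product is None:
                    fh.write(f"{o.offspring_id}\t1\t.\t.\t.\n")
                    continue
                cos = ",".join(map(str, o.product.co_positions)) or "."
                tr = list(o.product.tracts)
                if o.product.jackpot_tract:
                    tr.append(o.product.jackpot_tract)
                tracts = ",".join(f"{a}-{b}" for a, b in tr) or "."
                jid = o.jackpot_id if o.jackpot_id is not None else "."
                fh.write(f"{o.offspring_id}\t0\t{jid}\t{cos}\t{tracts}\n")
        for name in ("genotypes.tsv", "coverage.tsv", "truth.tsv"):
            record(out / name)

        # ---- call ----
        stage = "call"
        all_events = []
        ndj_calls = []
        n_unresolved = 0
        sel_interval = config.scheme.interval
        for o in offspring:
            ndj = detect_nondisjunction(o.observation, config.y_cov_threshold)
            ndj_calls.append(ndj)
            if ndj.is_nondisjunction:
                continue  # both maternal homologs present: origin calls invalid
            vec = assign_parental_origin(o.observation, panel)
            res = call_events(vec, panel, config.min_support_co, config.max_ncogc_span)
            n_unresolved += len(res.unresolved)
            events = restrict_to_selected_interval(
                res.events, sel_interval, o.observation.selection_class
            )
            all_events.extend(events)
        invio.write_events_bed(all_events, out / "events.tsv", config.chrom)
        record(out / "events.tsv")
        jackpots = find_jackpots(all_events)
        n_ndj = sum(1 for c in ndj_calls if c.is_nondisjunction)
        summary = {
            "n_offspring": len(offspring),
            "n_ndj": n_ndj,
            "n_co": sum(1 for e in all_events if e.event_class == "CO"),
            "n_co_excluded": sum(
                1 for e in all_events if e.event_class == "CO" and e.excluded
            ),
            "n_ncogc": sum(1 for e in all_events if e.event_class == "NCOGC"),
            "n_unresolved": n_unresolved,
            "jackpot_groups": [
                {"offspring": list(g.offspring_ids), "sites": list(g.converted_sites)}
                for g in jackpots
            ],
        }
        (out / "events_summary.json").write_text(json.dumps(summary, indent=2))
        record(out / "events_summary.json")

        # ---- stats ----
        stage = "stats"
        interval = config.analysis_interval or (
            config.model.breakpoint_proximal,
            config.scheme.markers.get("f", config.chrom_length),
        )
        cos = [e for e in all_events if e.event_class == "CO" and not e.excluded]
        windows = bin_and_normalize(
            cos, interval, config.stats_window, breakpoint=config.model.breakpoint_proximal
        )
        try:
            sp = spearman_distance_corr(windows)
            spearman = {"r": sp.r, "p": sp.p, "p_text": format_p(sp.p)}
        except ValueError:
            spearman = None
        n_recomb_pheno = sum(
            1 for o in offspring if o.observation.selection_class == "recombinant"
        )
        stats_out = {
            "map_estimate": None,
            "windows": [dataclasses.asdict(w) for w in windows],
            "spearman_distance": spearman,
            "n_ncogc": summary["n_ncogc"],
        }
        if config.scheme.mode is None:
            est = map_length_cM(n_recomb_pheno, len(offspring), name="-".join(config.scheme.select))
            stats_out["map_estimate"] = dataclasses.asdict(est)
        (out / "stats.json").write_text(json.dumps(stats_out, indent=2, allow_nan=True))
        record(out / "stats.json")
    except Exception:
        manifest.failed_stage = stage
        manifest.finished = time.time()
        (out / "manifest.json").write_text(manifest.to_json())
        raise

    manifest.finished = time.time()
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
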