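"""End-to-end orchestration: simulate -> detect -> metrics -> structure.

One global seed fans out deterministically to per-stage child streams;
every run writes a manifest recording inputs, parameters and artifact
checksums so a rerun with the same config reproduces identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import pandas as pd

from editscan import __version__
from editscan.detect import (
    DetectionParams,
    build_pileup,
    detect_sites,
    mismatch_spectrum,
    write_site_table,
)
from editscan.fold import DEFAULT_MODEL, site_stability
from editscan.genome import Genome
from editscan.metrics import editing_index, neighbor_motif
from editscan.simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "editscan_run"
    # either simulate...
    simulation: Optional[SimulationConfig] = None
    # ...or consume existing inputs
    genome_path: Optional[str] = None
    rna_sam: Optional[str] = None
    dna_sam: Optional[str] = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    flank: int = 400
    temperatures_c: List[float] = field(default_factory=lambda: [30.0])
    max_window: Optional[int] = None
    structure_max_sites: Optional[int] = 200
    motif_flank: int = 1
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.simulation is None:
            for path in (self.genome_path, self.rna_sam, self.dna_sam):
                if path is None or not os.path.exists(path):
                    raise FileNotFoundError(f"missing input {path!r}")
        for t in self.temperatures_c:
            if not (t == t and abs(t) < 1e6):
                raise ValueError("temperature must be finite")


def _parse_scalar(text: str):
    text = text.strip()
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def _parse_level_distribution(text: str) -> Mapping:
    name, _, args = text.partition(":")
    values = [float(x) for x in args.split(",")] if args else []
    if name == "uniform":
        return {"name": "uniform", "low": values[0], "high": values[1]}
    if name == "fixed":
        return {"name": "fixed", "value": values[0]}
    if name == "two_point":
        half = len(values) // 2
        return {"name": "two_point", "values": values[:half], "probs": values[half:]}
    raise ValueError(f"unknown level distribution {text!r}")


def load_config(path: str) -> PipelineConfig:
    """Read a flat ``key = value`` config file (``#`` starts a comment)."""
    raw: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()

    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    det_fields = {f.name for f in dataclasses.fields(DetectionParams)}
    sim_kwargs: Dict = {}
    det_kwargs: Dict = {}
    pipe_kwargs: Dict = {}
    for key, value in raw.items():
        if key == "seed":
            pipe_kwargs[key] = _parse_scalar(value)
        elif key in ("contig_lengths", "temperatures_c"):
            parsed = [_parse_scalar(v) for v in value.split(",")]
            (sim_kwargs if key == "contig_lengths" else pipe_kwargs)[key] = parsed
        elif key == "level_distribution":
            sim_kwargs[key] = _parse_level_distribution(value)
        elif key in sim_fields:
            sim_kwargs[key] = _parse_scalar(value)
        elif key in det_fields:
            det_kwargs[key] = _parse_scalar(value)
        else:
            pipe_kwargs[key] = _parse_scalar(value)

    seed = int(pipe_kwargs.get("seed", 0))
    simulation = None
    if sim_kwargs or not pipe_kwargs.get("genome_path"):
        simulation = SimulationConfig(seed=seed, **sim_kwargs)
    allowed = {f.name for f in dataclasses.fields(PipelineConfig)}
    pipe_kwargs = {k: v for k, v in pipe_kwargs.items() if k in allowed}
    return PipelineConfig(
        simulation=simulation, detection=DetectionParams(**det_kwargs), **pipe_kwargs
    )


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages under one run directory; returns the manifest."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: Dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "artifacts": {},
        "status": "running",
    }
    manifest["parameters"] = {
        "detection": dataclasses.asdict(config.detection),
        "flank": config.flank,
        "temperatures_c": config.temperatures_c,
        "max_window": config.max_window,
    }
    if config.simulation is not None:
        sim_dict = dataclasses.asdict(config.simulation)
        sim_dict["level_distribution"] = dict(sim_dict["level_distribution"])
        manifest["parameters"]["simulation"] = sim_dict
    manifest_path = os.path.join(config.outdir, "manifest.json")

    def _record(stage: str, outputs: Dict[str, str], rows: Optional[int] = None) -> None:
        manifest["stages"][stage] = {"rows": rows}
        for name, path in outputs.items():
            manifest["artifacts"][name] = {
                "path": path,
                "sha256": _sha256(path) if os.path.exists(path) else None,
            }

    def _fail(stage: str, exc: BaseException):
        manifest["status"] = f"failed at {stage}"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise PipelineError(stage, exc) from exc

    # ---------------------------------------------------------- simulate
    stage = "simulate"
    try:
        if config.simulation is not None:
            paths = simulate_dataset(config.simulation, os.path.join(config.outdir, "simulate"))
            genome_path, rna_sam, dna_sam = paths["genome"], paths["rna_sam"], paths["dna_sam"]
            _record(stage, paths, rows=config.simulation.n_sites)
        else:
            genome_path, rna_sam, dna_sam = config.genome_path, config.rna_sam, config.dna_sam
            _record(stage, {}, rows=0)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        _fail(stage, exc)

    # ------------------------------------------------------------ detect
    stage = "detect"
    try:
        genome = Genome.from_fasta(genome_path)
        rna_pileup = build_pileup(rna_sam, genome, config.detection.base_quality_min)
        dna_pileup = build_pileup(dna_sam, genome, config.detection.base_quality_min)
        sites = detect_sites(rna_pileup, dna_pileup, genome, config.detection)
        sites_path = os.path.join(config.outdir, "sites.tsv")
        write_site_table(sites, sites_path)
        _record(stage, {"sites": sites_path}, rows=len(sites))
    except Exception as exc:  # noqa: BLE001
        _fail(stage, exc)

    # ------------------------------------------------------------- index
    stage = "index"
    try:
        result = editing_index(rna_pileup, genome)
        spectrum, ag_fraction = mismatch_spectrum(sites)
        index_path = os.path.join(config.outdir, "index.json")
        with open(index_path, "w") as fh:
            json.dump(
                {
                    "per_class": result.to_dict(),
                    "index_percent": (result.index if result.denominator else None),
                    "mismatch_spectrum": spectrum,
                    "ag_fraction": ag_fraction,
                },
                fh,
                indent=2,
            )
        _record(stage, {"index": index_path}, rows=len(result.per_class))
    except Exception as exc:  # noqa: BLE001
        _fail(stage, exc)

    # ------------------------------------------------------------- motif
    stage = "motif"
    try:
        motif_path = os.path.join(config.outdir, "motif.tsv")
        if len(sites):
            motif = neighbor_motif(sites, genome, k=config.motif_flank)
            table = motif.frequencies.copy()
            table.columns = [f"site_{c}" for c in table.columns]
            for base in motif.background.columns:
                table[f"background_{base}"] = motif.background[base]
            table.index.name = "offset"
            table.to_csv(motif_path, sep="\t")
        else:
            pd.DataFrame().to_csv(motif_path, sep="\t")
        _record(stage, {"motif": motif_path}, rows=len(sites))
    except Exception as exc:  # noqa: BLE001
        _fail(stage, exc)

    # --------------------------------------------------------- structure
    stage = "structure"
    try:
        fold_sites = sites
        if config.structure_max_sites is not None:
            fold_sites = sites.head(config.structure_max_sites)
        for temp_c in config.temperatures_c:
            profile = site_stability(
                genome,
                fold_sites,
                flank=config.flank,
                temperature_c=temp_c,
                model=DEFAULT_MODEL,
                max_window=config.max_window,
            )
            path = os.path.join(config.outdir, f"structure_T{temp_c:g}.tsv")
            profile.to_csv(path, sep="\t", index=False)
            _record(f"{stage}_T{temp_c:g}", {f"structure_T{temp_c:g}": path}, rows=len(profile))
    except Exception as exc:  # noqa: BLE001
        _fail(stage, exc)

    manifest["status"] = "ok"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
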