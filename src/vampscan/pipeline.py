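"""Stage orchestration: validated config, ordered execution, run manifest.

A run config is a plain mapping (usually loaded from YAML) with one
section per stage plus global ``seed`` and ``outdir`` keys.  Unknown
keys anywhere are rejected before any stage runs.  Every stage writes
its outputs under the run directory and records them, with content
digests, in ``manifest.json``; identical configs reproduce identical
digests for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import abundance_scoring, atlas_analysis, degron_scoring, io, library_design
from . import subassembly as sub
from . import synthetic_data as synth
from .variants import DesignError, ProteinSequence

STAGE_ORDER = ["design", "simulate", "subassemble", "score", "tiles", "analyze"]

_GLOBAL_KEYS = {"seed", "outdir"}
_STAGE_KEYS: dict[str, set[str]] = {
    "design": {
        "fasta", "sequence", "identifier", "tile_len", "tile_step",
        "include_nonsense", "nonsense_excluded_positions", "include_wild_type",
    },
    "simulate": {
        "mean_barcodes_per_variant", "cells_per_barcode", "depth_per_gate",
        "n_biological", "n_technical", "noise_sd", "fraction_low", "n_gates",
        "simulate_reads", "reads_per_barcode", "sub_rate", "indel_rate",
    },
    "subassemble": {"reads_fasta", "max_subs"},
    "score": {"counts", "barcode_map", "pool_synonymous_wt", "min_reads_per_barcode"},
    "tiles": {
        "tile_counts", "control_ids", "reference_library",
        "contaminant_filter",
    },
    "analyze": {
        "scores", "labels", "external", "min_n_per_position",
        "low_abundance_threshold",
    },
}


class ConfigError(ValueError):
    """Raised when a run config fails validation."""


class DependencyError(RuntimeError):
    """Raised when a stage's upstream output is missing."""


def validate_config(config: dict) -> dict:
    """Reject unknown keys and fill defaults; returns the config unchanged."""
    unknown = set(config) - _GLOBAL_KEYS - set(_STAGE_KEYS)
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    for stage, section in config.items():
        if stage in _GLOBAL_KEYS:
            continue
        if not isinstance(section, dict):
            raise ConfigError(f"stage section {stage!r} must be a mapping")
        bad = set(section) - _STAGE_KEYS[stage]
        if bad:
            raise ConfigError(f"unknown keys in stage {stage!r}: {sorted(bad)}")
    if "seed" in config and not isinstance(config["seed"], int):
        raise ConfigError("seed must be an integer")
    return config


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    seed: int
    stages_run: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def record(self, path: Path, outdir: Path) -> None:
        self.outputs[str(path.relative_to(outdir))] = _digest(path)

    def write(self, outdir: Path) -> Path:
        path = outdir / "manifest.json"
        path.write_text(
            json.dumps(
                {"seed": self.seed, "stages": self.stages_run, "outputs": self.outputs},
                indent=2,
                sort_keys=True,
            )
        )
        return path


def _load_protein(section: dict, outdir: Path) -> ProteinSequence:
    if "fasta" in section:
        return io.read_protein_fasta(section["fasta"])
    if "sequence" in section:
        return ProteinSequence(section.get("identifier", "protein"), section["sequence"])
    design_csv = outdir / "design_space.csv"
    raise DependencyError(
        f"stage needs a protein: give design.fasta or design.sequence ({design_csv} absent)"
    )


def run_pipeline(
    config: dict, stages: list[str] | None = None, outdir: str | Path | None = None
) -> RunManifest:
    """Execute the requested stages in dependency order.

    ``stages`` defaults to every stage with a config section, run in
    the canonical order.  Intermediate products are exchanged through
    files in ``outdir`` so each stage consumes only declared inputs.
    """
    validate_config(config)
    outdir = Path(outdir or config.get("outdir", "vampscan-run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    if stages is None:
        stages = [s for s in STAGE_ORDER if s in config]
    else:
        bad = set(stages) - set(STAGE_ORDER)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")
        stages = [s for s in STAGE_ORDER if s in stages]
    manifest = RunManifest(seed=seed)

    for stage in stages:
        section = dict(config.get(stage, {}))
        handler = _HANDLERS[stage]
        written = handler(section, config, outdir, seed)
        manifest.stages_run.append(stage)
        for path in written:
            manifest.record(path, outdir)
    manifest.write(outdir)
    return manifest


def _require(path: Path, stage: str, hint: str) -> Path:
    if not path.exists():
        raise DependencyError(f"stage {stage!r} needs {path.name}: {hint}")
    return path


def _stage_design(section, config, outdir: Path, seed: int) -> list[Path]:
    seq = _load_protein(section, outdir)
    design = library_design.enumerate_design_space(
        seq,
        include_nonsense=section.get("include_nonsense", True),
        nonsense_excluded_positions=section.get("nonsense_excluded_positions", (1,)),
        include_wild_type=section.get("include_wild_type", True),
    )
    tiles = library_design.partition_tiles(
        library_design.tile_protein(
            seq, section.get("tile_len", 24), section.get("tile_step", 12)
        )
    )
    oligos = library_design.build_tile_oligos(tiles)
    paths = []
    io.write_table(design.to_frame(), outdir / "design_space.csv")
    io.write_table(library_design.tiles_to_frame(tiles), outdir / "tiles.csv")
    io.write_table(
        pd.DataFrame(
            {
                "name": [o.name for o in oligos],
                "library": [o.library for o in oligos],
                "core_nt_length": [o.core_nt_length for o in oligos],
                "oligo_nt_length": [o.adaptored_nt_length for o in oligos],
                "sequence": [o.sequence for o in oligos],
            }
        ),
        outdir / "oligos.csv",
    )
    (outdir / "protein.fasta").write_text(f">{seq.identifier}\n{seq.residues}\n")
    paths += [
        outdir / "design_space.csv",
        outdir / "tiles.csv",
        outdir / "oligos.csv",
        outdir / "protein.fasta",
    ]
    return paths


def _design_from_csv(outdir: Path, stage: str) -> library_design.DesignSpace:
    from .variants import VariantId

    path = _require(outdir / "design_space.csv", stage, "run the design stage first")
    frame = io.read_table(path)
    return library_design.DesignSpace(
        [VariantId.from_string(v) for v in frame["variant"]]
    )


def _stage_simulate(section, config, outdir: Path, seed: int) -> list[Path]:
    design = _design_from_csv(outdir, "simulate")
    exp = synth.simulate_experiment(
        design,
        mean_barcodes_per_variant=section.get("mean_barcodes_per_variant", 24.0),
        cells_per_barcode=section.get("cells_per_barcode", 50),
        depth_per_gate=section.get("depth_per_gate"),
        n_biological=section.get("n_biological", 2),
        n_technical=section.get("n_technical", 2),
        noise_sd=section.get("noise_sd", 0.25),
        fraction_low=section.get("fraction_low", 0.28),
        n_gates=section.get("n_gates", 4),
        seed=seed,
    )
    io.write_table(exp.counts, outdir / "counts.csv")
    io.write_table(exp.barcode_map, outdir / "barcode_map_truth.csv")
    io.write_table(exp.true_scores, outdir / "true_scores.csv")
    (outdir / "simulation_params.json").write_text(
        json.dumps({"seed": seed, **exp.params}, indent=2, sort_keys=True)
    )
    paths = [
        outdir / "counts.csv",
        outdir / "barcode_map_truth.csv",
        outdir / "true_scores.csv",
        outdir / "simulation_params.json",
    ]
    if section.get("simulate_reads", False):
        protein = io.read_protein_fasta(
            _require(outdir / "protein.fasta", "simulate", "run the design stage first")
        )
        from .codons import reverse_translate

        reads, truth = synth.simulate_long_reads(
            exp.barcode_map,
            reverse_translate(protein.residues),
            reads_per_barcode=section.get("reads_per_barcode", 3),
            sub_rate=section.get("sub_rate", 0.002),
            indel_rate=section.get("indel_rate", 0.01),
            seed=seed + 1,
        )
        io.write_reads_fasta(reads, outdir / "longreads.fasta")
        io.write_table(truth, outdir / "longreads_truth.csv")
        paths += [outdir / "longreads.fasta", outdir / "longreads_truth.csv"]
    return paths


def _stage_subassemble(section, config, outdir: Path, seed: int) -> list[Path]:
    reads_path = Path(
        section.get("reads_fasta", outdir / "longreads.fasta")
    )
    _require(reads_path, "subassemble", "simulate reads or point reads_fasta at a file")
    protein = io.read_protein_fasta(
        _require(outdir / "protein.fasta", "subassemble", "run the design stage first")
    )
    from .codons import reverse_translate

    reads = io.read_reads_fasta(reads_path)
    bc_map, stats = sub.build_barcode_map(
        reads,
        synth.ConstructLayout(),
        reverse_translate(protein.residues),
        max_subs=section.get("max_subs", 10),
    )
    io.write_table(bc_map, outdir / "barcode_map.csv")
    (outdir / "subassembly_stats.json").write_text(
        json.dumps(stats.as_dict(), indent=2, sort_keys=True)
    )
    return [outdir / "barcode_map.csv", outdir / "subassembly_stats.json"]


def _stage_score(section, config, outdir: Path, seed: int) -> list[Path]:
    counts_path = Path(section.get("counts", outdir / "counts.csv"))
    map_path = Path(section.get("barcode_map", outdir / "barcode_map_truth.csv"))
    _require(counts_path, "score", "run the simulate stage or point counts at a file")
    _require(map_path, "score", "run simulate/subassemble or point barcode_map at a file")
    counts = io.read_table(counts_path)
    bc_map = io.read_table(map_path)
    result = abundance_scoring.score_counts(
        counts,
        bc_map,
        pool_synonymous_wt=section.get("pool_synonymous_wt", False),
        min_reads_per_barcode=section.get("min_reads_per_barcode", 0),
    )
    io.write_table(result.scores, outdir / "scores.csv")
    io.write_table(result.per_replicate, outdir / "scores_per_replicate.csv")
    qc = {"psi_wt": result.psi_wt, "psi_stop": result.psi_stop}
    try:
        qc_table = abundance_scoring.replicate_qc(result.per_replicate)
        qc["replicate_pearson"] = qc_table.to_dict(orient="records")
    except abundance_scoring.ScoringError:
        qc["replicate_pearson"] = []
    (outdir / "score_qc.json").write_text(json.dumps(qc, indent=2, sort_keys=True))
    return [
        outdir / "scores.csv",
        outdir / "scores_per_replicate.csv",
        outdir / "score_qc.json",
    ]


def _stage_tiles(section, config, outdir: Path, seed: int) -> list[Path]:
    counts_path = Path(section.get("tile_counts", outdir / "tile_counts.csv"))
    _require(counts_path, "tiles", "provide tiles.tile_counts")
    tiles_path = _require(outdir / "tiles.csv", "tiles", "run the design stage first")
    counts = io.read_table(counts_path)
    tile_frame = io.read_table(tiles_path)
    lib_of = dict(zip(tile_frame["tile"], tile_frame["library"]))
    for tile in counts["tile"].unique():
        if tile.startswith("ctrl-"):
            lib_of[tile] = library_design.CONTROL
    if section.get("contaminant_filter", True):
        counts = degron_scoring.remove_contaminants(counts, lib_of)
    tsi_by_library = {
        lib: degron_scoring.average_tsi(degron_scoring.tsi_per_tile(grp))
        for lib, grp in counts.groupby("run_library")
    }
    control_ids = section.get("control_ids", ["ctrl-RLLL", "ctrl-DAAA"])
    combined, fits = degron_scoring.renormalize_libraries(
        tsi_by_library, control_ids, reference=section.get("reference_library", "Odds")
    )
    io.write_table(combined, outdir / "tsi.csv")
    tiles = [
        library_design.Tile(
            int(r["index"]), int(r["start"]), int(r["end"]), r["peptide"], r["library"]
        )
        for _, r in tile_frame.iterrows()
    ]
    profile = degron_scoring.assign_tsi_to_positions(
        combined[combined["library"] != library_design.CONTROL], tiles
    )
    io.write_table(profile, outdir / "tsi_profile.csv")
    (outdir / "tile_fits.json").write_text(
        json.dumps(
            {
                lib: {"slope": f.slope, "intercept": f.intercept,
                      "controls": list(f.control_ids)}
                for lib, f in fits.items()
            },
            indent=2,
            sort_keys=True,
        )
    )
    return [outdir / "tsi.csv", outdir / "tsi_profile.csv", outdir / "tile_fits.json"]


def _stage_analyze(section, config, outdir: Path, seed: int) -> list[Path]:
    scores_path = Path(section.get("scores", outdir / "scores.csv"))
    _require(scores_path, "analyze", "run the score stage or point scores at a file")
    protein = io.read_protein_fasta(
        _require(outdir / "protein.fasta", "analyze", "run the design stage first")
    )
    scores = io.read_table(scores_path)
    emap = atlas_analysis.build_effect_map(scores, protein)
    medians = atlas_analysis.position_medians(
        emap, min_n=section.get("min_n_per_position", 17)
    )
    flagged = atlas_analysis.classify_low_abundance(
        scores, threshold=section.get("low_abundance_threshold", 0.5)
    )
    report = {
        "coverage": emap.coverage,
        "n_scored": emap.n_scored,
        "n_possible": emap.n_possible,
        "n_low_abundance": flagged.attrs["n_low"],
        "fraction_low_abundance": flagged.attrs["fraction_low"],
    }
    if "labels" in section:
        labels = io.read_table(section["labels"])
        roc = atlas_analysis.roc_auc(scores, labels)
        io.write_table(
            pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}), outdir / "roc_points.csv"
        )
        report["auc"] = roc.auc
        report["n_pathogenic"] = roc.n_positive
        report["n_benign"] = roc.n_negative
    emap.scores.to_csv(outdir / "effect_map.csv")
    io.write_table(medians, outdir / "position_medians.csv")
    (outdir / "analysis_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True)
    )
    paths = [
        outdir / "effect_map.csv",
        outdir / "position_medians.csv",
        outdir / "analysis_report.json",
    ]
    if "labels" in section:
        paths.append(outdir / "roc_points.csv")
    return paths


_HANDLERS = {
    "design": _stage_design,
    "simulate": _stage_simulate,
    "subassemble": _stage_subassemble,
    "score": _stage_score,
    "tiles": _stage_tiles,
    "analyze": _stage_analyze,
}
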