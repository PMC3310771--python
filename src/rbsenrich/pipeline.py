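"""End-to-end orchestration: filter -> SD analysis -> rRNA scan -> motif
search -> co-occurrence -> structure scan.

A run is a pure function of (inputs, RunConfig): all randomness flows from
one master seed through named per-stage substreams, so stage order and
library member order never affect results, and reruns with the same config
are byte-identical.  Every run writes a manifest with the config, a config
hash, and per-stage record counts.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import motifs as motif_mod
from . import rrna as rrna_mod
from . import sd as sd_mod
from . import structure as struct_mod
from .library import UTRLibrary
from .reads import FilterReport, ReadTemplate, filter_reads, read_sequences

ALL_STAGES = ("filter", "sd", "rrna", "motifs", "cooccur", "structure")

# fixed substream indices per stage; independent of which stages run
_STAGE_STREAM = {"simulate": 0, "rrna": 1, "motifs": 2, "structure": 3}


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stable 31-bit per-stage seed from the master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STAGE_STREAM[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    reads_path: str | None = None
    library_path: str | None = None
    rrna_paths: list[str] = field(default_factory=list)
    out_dir: str = "rbs_enrich_out"
    region_length: int = 18
    extended_sd_set: bool = False
    k_range: tuple[int, int] = (4, 8)
    replicates: int = 1000
    seed: int = 0
    alpha: float = 0.01
    fdr: float = 0.01
    unique: bool = False
    stages: tuple[str, ...] = ALL_STAGES
    simulated_n: int = 10_000
    motif_method: str = "empirical"

    def __post_init__(self):
        for thr in (self.alpha, self.fdr):
            if not 0.0 < thr < 1.0:
                raise ValueError("thresholds must be in (0,1)")
        lo, hi = self.k_range
        if not 1 <= lo <= hi <= self.region_length:
            raise ValueError("k_range must lie within [1, region_length]")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_library(config: RunConfig) -> tuple[UTRLibrary, FilterReport | None]:
    if config.reads_path:
        reads = read_sequences(config.reads_path)
        library, report = filter_reads(reads, ReadTemplate(), config.region_length)
        return library, report
    if config.library_path:
        return UTRLibrary.from_fasta(config.library_path), None
    raise ValueError("config must provide reads_path or library_path")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the report bundle (also on disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ks = list(range(config.k_range[0], config.k_range[1] + 1))
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    bundle: dict = {"manifest": manifest}

    def log_stage(name: str, t0: float, **counts):
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            **counts,
        }

    t0 = time.perf_counter()
    library, report = _load_library(config)
    if config.unique:
        library = library.collapse_unique()
    bundle["library"] = library
    if "filter" in config.stages and report is not None:
        report.to_tsv(out / "filter_report.tsv")
        bundle["filter_report"] = report
    library.to_fasta(out / "library.fasta")
    log_stage("filter", t0, reads=library.total, unique=library.n_unique)

    motif_set = (
        sd_mod.SDMotifSet.extended() if config.extended_sd_set else sd_mod.SDMotifSet.core()
    )
    if "sd" in config.stages and library.total:
        t0 = time.perf_counter()
        table = sd_mod.classification_table(library, motif_set)
        table.to_csv(out / "sd_classification.tsv", sep="\t", index=False)
        sd_lib, non_sd_lib = sd_mod.partition_library(library, motif_set)
        comp = sd_mod.base_composition_by_position(library)
        comp.to_csv(out / "base_composition.tsv", sep="\t")
        hist = sd_mod.cytosine_histogram(library)
        hist.to_frame().to_csv(out / "cytosine_histogram.tsv", sep="\t", index=False)
        profiles = [
            sd_mod.positional_motif_frequency(library, m).to_frame().assign(motif=m)
            for m in motif_set.motifs
        ]
        import pandas as pd

        pd.concat(profiles, ignore_index=True).to_csv(
            out / "sd_positional_profiles.tsv", sep="\t", index=False
        )
        bundle.update(sd_lib=sd_lib, non_sd_lib=non_sd_lib, composition=comp)
        log_stage("sd", t0, sd=sd_lib.total, non_sd=non_sd_lib.total)

    if "rrna" in config.stages and config.rrna_paths and library.total:
        t0 = time.perf_counter()
        scans = []
        n_sig = 0
        for path in config.rrna_paths:
            for rrna in rrna_mod.RRNASequence.from_fasta(path):
                frame = rrna_mod.rrna_scan(
                    library,
                    rrna,
                    ks,
                    replicates=config.replicates,
                    seed=stage_seed(config.seed, "rrna"),
                    alpha=config.alpha,
                )
                frame.to_csv(out / f"rrna_scan_{rrna.name}.tsv", sep="\t", index=False)
                if 7 in ks:
                    groups = rrna_mod.group_significant_windows(frame, k=7)
                    rrna_mod.groups_to_bed(groups, out / f"rrna_groups_{rrna.name}.bed")
                n_sig += int(frame["significant"].sum())
                scans.append(frame)
        bundle["rrna_scans"] = scans
        log_stage("rrna", t0, significant_windows=n_sig)

    if "motifs" in config.stages and library.total:
        t0 = time.perf_counter()
        frames = []
        for k in ks:
            frame = motif_mod.motif_significance(
                library,
                k,
                replicates=config.replicates,
                seed=stage_seed(config.seed, "motifs") + k,
                method=config.motif_method,
                fdr=config.fdr,
            )
            frame.to_csv(out / f"motifs_k{k}.tsv", sep="\t", index=False)
            frames.append(frame)
        bundle["motif_frames"] = frames
        log_stage("motifs", t0, families=len(frames))

        if "cooccur" in config.stages:
            t0 = time.perf_counter()
            import pandas as pd

            significant = pd.concat(frames, ignore_index=True)
            significant = significant[significant["significant"]]["motif"].tolist()
            cooc = motif_mod.cooccurrence_table(library, significant)
            cooc.to_csv(out / "cooccurrence.tsv", sep="\t", index=False)
            bundle["cooccurrence"] = cooc
            log_stage("cooccur", t0, pairs=len(cooc), motifs=len(significant))

    if "structure" in config.stages and library.total:
        t0 = time.perf_counter()
        profile = struct_mod.dG_profile(
            library,
            simulated_n=config.simulated_n,
            seed=stage_seed(config.seed, "structure"),
        )
        profile["library_records"].to_csv(
            out / "structure_windows.tsv", sep="\t", index=False
        )
        profile["summary"].to_csv(out / "structure_summary.tsv", sep="\t", index=False)
        bundle["structure"] = profile
        log_stage("structure", t0, molecules=library.n_unique)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return bundle


def summarize(bundle: dict) -> str:
    """One-page text summary of a report bundle."""
    lines = ["RBS enrichment analysis summary", "=" * 32]
    missing = []
    library: UTRLibrary | None = bundle.get("library")
    if library is not None:
        lines.append(f"library: {library.total} reads, {library.n_unique} unique")
    else:
        missing.append("library")
    report: FilterReport | None = bundle.get("filter_report")
    if report is not None:
        lines.append(
            f"filtering: {report.accepted}/{report.total_reads} accepted "
            f"(length {report.rejected_length}, flank "
            f"{report.rejected_flank + report.rejected_no_locus}, "
            f"in-frame ATG {report.rejected_inframe_start})"
        )
    if "sd_lib" in bundle and library is not None and library.total:
        sd_lib, non_sd = bundle["sd_lib"], bundle["non_sd_lib"]
        frac = sd_lib.total / library.total
        lines.append(f"SD fraction: {frac:.3f} ({sd_lib.total}/{library.total})")
        hist = sd_mod.cytosine_histogram(non_sd) if non_sd.total else None
        if hist:
            lines.append(
                f"non-SD with >=9 C: {hist.fraction_at_least(9):.3f} "
                f"of {non_sd.total}"
            )
    elif library is not None and library.total:
        missing.append("sd")
    if "motif_frames" in bundle:
        import pandas as pd

        k5 = [f for f in bundle["motif_frames"] if (f["k"] == 5).all()]
        frame = k5[0] if k5 else bundle["motif_frames"][0]
        top = motif_mod.top_motifs(frame, 10)
        lines.append("top motifs (frequency): " + ", ".join(
            f"{m} {f:.3f}" for m, f in top
        ))
    if "rrna_scans" in bundle:
        for frame in bundle["rrna_scans"]:
            name = frame["rrna_name"].iloc[0]
            per_k = frame.groupby("k")["significant"].sum()
            desc = ", ".join(f"k={k}: {int(v)}" for k, v in per_k.items())
            groups = rrna_mod.group_significant_windows(frame, k=7) if 7 in per_k.index else []
            lines.append(f"rRNA {name}: significant windows {desc}; 7-mer groups: {len(groups)}")
    if "structure" in bundle:
        summ = bundle["structure"]["summary"]
        med = summ[summ["set"] == "library"]["median_dG"].tolist()
        lines.append(
            "structure median dG per window: "
            + ", ".join(f"{v:.1f}" for v in med)
        )
    if library is not None and library.total == 0:
        lines.append("library empty: all downstream counts are zero")
    if missing:
        lines.append("missing stage outputs: " + ", ".join(missing))
    return "\n".join(lines) + "\n"
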