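"""End-to-end orchestration: one config in, a reproducible report bundle out.

Stages: ingest (or synthesize) alignment + sample table, collapse to the
318-bp frame, distances, per-sample diversity/neutrality table, pairwise
ΦST matrix, SAMOVA grouping + AMOVA decomposition, Mantel isolation by
distance, pooled mismatch/sudden-expansion fit (plus pooled Fu's Fs),
median-joining network, and optional ABC scenario choice.  Every stage is a
pure function of (inputs, config, seeds); the manifest records seeds, input
checksums and wall times so reruns can be verified bitwise (timestamps
aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as div
from .alignment import read_alignment, truncate_frame, variable_sites, write_alignment
from .distance import pairwise_differences
from .mismatch import SuddenExpansionModel, mismatch_observed
from .network import export_network, median_joining
from .samples import (
    CONTEMPORARY,
    RegionalSample,
    pooled_sample,
    read_sample_table,
    tabulate_regions,
    write_count_matrix,
)
from .structure import Amova, MantelIBD, Samova, phist_matrix

logger = logging.getLogger("gulo_phylogeo")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Inputs, analysis windows and permutation/simulation effort."""

    fasta: str | None = None
    sample_table: str | None = None
    synthetic_seed: int | None = None  # used when no input files are given
    output_dir: str = "gulo_phylogeo_out"
    frame_start: int = 1
    frame_end: int | None = None
    gap_mode: str = "exclude"
    merge_eras: bool = False
    rarefy_g: int = 6
    rarefy_g_historic: int = 5
    nsim_neutrality: int = 1000
    nperm_phist: int = 1000
    nperm_amova: int = 10_100
    samova_k: int = 3
    samova_n_init: int = 10
    samova_n_iter: int = 500
    ibd_min_n: int = 10
    mismatch_nboot: int = 100
    run_abc: bool = False
    abc_n_sim: int = 1000
    abc_accept: float = 0.01
    seed: int = 1

    def validate(self) -> None:
        for p in (self.fasta, self.sample_table):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if (self.fasta is None) != (self.sample_table is None):
            raise ValueError("provide both --fasta and --samples, or neither")
        if self.fasta is None and self.synthetic_seed is None:
            raise ValueError("no inputs: set synthetic_seed to generate a dataset")
        if self.gap_mode not in ("exclude", "fifth_state"):
            raise ValueError(f"unknown gap_mode {self.gap_mode!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(manifest: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            dt = time.perf_counter() - self.t0
            manifest["stages"][name] = round(dt, 3)
            logger.info("stage=%s wall_s=%.2f", name, dt)

    return _Timer()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to the bundle)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "stages": {},
        "inputs": {},
        "version": _package_version(),
    }

    with _stage(manifest, "ingest"):
        if config.fasta is not None:
            aln = read_alignment(config.fasta)
            records = read_sample_table(config.sample_table)
            manifest["inputs"]["fasta_sha256"] = _sha256(Path(config.fasta))
            manifest["inputs"]["samples_sha256"] = _sha256(Path(config.sample_table))
        else:
            from .synthetic import make_study_like

            aln, records, report = make_study_like(seed=config.synthetic_seed)
            manifest["inputs"]["synthetic_seed"] = config.synthetic_seed
            manifest["inputs"]["synthetic_report"] = report
        end = config.frame_end or aln.L
        if (config.frame_start, end) != (1, aln.L):
            aln = truncate_frame(aln, config.frame_start, end)
        if config.merge_eras:
            from .samples import SampleRecord

            records = [
                SampleRecord(r.individual_id, r.region, CONTEMPORARY, r.haplotype_id,
                             r.latitude, r.longitude)
                for r in records
            ]
        samples = tabulate_regions(records, known_haplotypes=set(aln.ids))
        regional = [s for s in samples if s.region != "ALL"]
        analyzable = [s for s in regional if s.n >= 2]  # singletons pooled only
        pooled = pooled_sample(regional)
        dist = pairwise_differences(aln, gap_mode=config.gap_mode)
        write_alignment(aln, out / "haplotypes.fasta")
        write_count_matrix(samples, out / "regional_counts.csv")

    with _stage(manifest, "diversity"):
        table = div.diversity_table(
            analyzable, dist, aln,
            g_contemporary=config.rarefy_g, g_historic=config.rarefy_g_historic,
            nsim=config.nsim_neutrality, seed=config.seed,
        )
        table.to_csv(out / "diversity.csv", index=False)

    with _stage(manifest, "phist"):
        phi = phist_matrix(analyzable, dist, nperm=config.nperm_phist, seed=config.seed)
        phi.to_csv(out / "phist.csv")

    with _stage(manifest, "samova_amova"):
        coords = {
            s.label: (s.latitude, s.longitude)
            for s in analyzable
            if s.latitude is not None
        }
        k = min(config.samova_k, len(analyzable))
        sam = Samova(analyzable, dist, coords=coords or None).fit(
            K=k, n_init=config.samova_n_init, n_iter=config.samova_n_iter,
            seed=config.seed,
        )
        grouping = {lab: str(g) for lab, g in sam.assignment.items()}
        amova_res = Amova(analyzable, dist, grouping=grouping).fit(
            nperm=config.nperm_amova, seed=config.seed
        )
        report = {
            "samova_K": sam.K,
            "samova_groups": sam.groups(),
            "phi_CT": sam.phi_CT,
            "amova": {
                "variance_components": amova_res.components,
                "percentages": amova_res.percentages,
                "phi_ST": amova_res.phi_ST,
                "phi_SC": amova_res.phi_SC,
                "phi_CT": amova_res.phi_CT,
                "p_values": amova_res.p_values,
            },
        }
        (out / "structure.json").write_text(json.dumps(report, indent=2))
        with open(out / "structure.txt", "w") as fh:
            fh.write(amova_res.summary().to_string(index=False) + "\n")

    with _stage(manifest, "ibd"):
        sizes = {s.label: s.n for s in analyzable}
        try:
            ibd = MantelIBD(
                phi, {s.label: (s.latitude, s.longitude) for s in analyzable},
                sample_sizes=sizes, min_n=config.ibd_min_n,
            ).fit(nperm=config.nperm_phist, seed=config.seed)
            ibd_out = {"r": ibd.r, "p": ibd.p, "n_populations": ibd.n_populations,
                       "n_pairs": ibd.n_pairs}
        except ValueError as exc:
            ibd_out = {"skipped": str(exc)}
        (out / "ibd.json").write_text(json.dumps(ibd_out, indent=2))

    with _stage(manifest, "mismatch"):
        obs = mismatch_observed(pooled, dist)
        fit = SuddenExpansionModel(obs, pooled.n).fit(
            nboot=config.mismatch_nboot, seed=config.seed
        )
        kbar = div.mean_pairwise_differences(pooled, dist)
        k_obs = len(pooled.haplotypes())
        fs_pooled = div.fus_fs_value(pooled.n, k_obs, kbar)
        (out / "mismatch.json").write_text(json.dumps({
            "tau": fit.tau, "theta0": fit.theta0, "theta1": fit.theta1,
            "ssd": fit.ssd, "p_ssd": fit.p_ssd,
            "raggedness": fit.raggedness, "p_raggedness": fit.p_raggedness,
            "pooled_fs": fs_pooled, "pooled_n": pooled.n,
            "pooled_haplotypes": k_obs,
        }, indent=2))
        fit.histogram().to_csv(out / "mismatch_histogram.csv", index=False)

    with _stage(manifest, "network"):
        region_freqs = {
            h: {s.label: s.counts.get(h, 0) for s in regional if s.counts.get(h, 0)}
            for h in aln.ids
        }
        net = median_joining(
            aln, freqs=pooled.counts, gap_mode=config.gap_mode,
            region_freqs=region_freqs,
        )
        export_network(net, out / "network.graphml", out / "network_edges.tsv")

    if config.run_abc:
        with _stage(manifest, "abc"):
            from .abc import AbcModelChoice, build_reference_table, observed_summaries
            from .scenarios import STUDY_SAMPLE_SIZES, default_scenarios

            obs_vec = observed_summaries(regional, aln, dist)
            table_ref = build_reference_table(
                default_scenarios(), config.abc_n_sim, STUDY_SAMPLE_SIZES,
                seed=config.seed,
            )
            res = AbcModelChoice(table_ref, obs_vec).fit(
                accept_fraction=config.abc_accept, seed=config.seed
            )
            (out / "abc.json").write_text(json.dumps({
                "posterior_probabilities": res.posterior_probabilities,
                "rejection_proportions": res.rejection_proportions,
                "selected": res.selected,
                "n_accepted": res.n_accepted,
                "used_fallback": res.used_fallback,
            }, indent=2))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("gulo-phylogeo")
    except Exception:
        return "unknown"
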