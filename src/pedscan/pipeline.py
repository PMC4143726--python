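"""Multiphase orchestration: adjust -> linkage scan -> region selection -> association.

``run_multiphase`` wires the three analysis phases together on files:

1. censored-regression phenotype adjustment per exam, averaged into R;
2. two-point variance-components linkage on randomly sampled common
   markers (one or more sampling rounds, later rounds excluding earlier
   picks), with LOD-based region selection;
3. MG + QTDT association on every variant falling inside a selected
   region (or a manual region override), optionally with the marker's IBD
   matrix as a linkage variance component.

Every random draw derives from the single config seed via phase-keyed
``numpy.random.SeedSequence`` spawning, so partial reruns are consistent
and full reruns byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path


import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import qq_diagnostics, results_to_frame, analyze_marker
from .genio import read_genotypes
from .ibd import (
    IbdSizeError,
    MendelianInconsistencyError,
    compute_ibd_exact,
    compute_ibd_montecarlo,
    estimate_allele_freq,
    prior_ibd,
    AlleleFrequencyError,
)
from .linkage import (
    fit_polygenic_null,
    fit_vc_linkage,
    fits_to_frame,
    regions_to_frame,
    sample_markers,
    select_regions,
)
from .pedigree import compute_kinship, read_pedigree
from .phenotype import build_adjusted_phenotype, fit_censored_exam, read_exam_csv

logger = logging.getLogger(__name__)

_PHASES = ("sample_markers", "ibd", "adjust", "assoc")


class PipelineError(RuntimeError):
    pass


def phase_seed(base_seed: int, phase: str, extra: int = 0) -> int:
    """Deterministic per-phase seed: SeedSequence(base, spawn_key=(phase#, extra))."""
    idx = _PHASES.index(phase)
    ss = np.random.SeedSequence(base_seed, spawn_key=(idx, extra))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    ped_path: str = ""
    pheno_path: str = ""
    gwas_geno_path: str = ""
    gwas_map_path: str | None = None
    seq_geno_path: str | None = None  # defaults to the GWAS genotype file
    seq_map_path: str | None = None
    out_dir: str = "pedscan_out"
    run_adjust: bool = True
    run_linkage: bool = True
    run_assoc: bool = True
    sample_sizes: tuple[int, ...] = (200,)
    maf_min: float = 0.05
    lod_threshold: float = 1.2
    merge_bp: int = 10_000_000
    assoc_region: str | None = None  # "chr:start-end" in bp, closed interval
    linkage_vc_in_assoc: bool = False
    mendelian_policy: str = "error"  # or "prior": blank Pi to 2*Phi, warn
    ibd_mc_samples: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lod_threshold <= 0 or self.merge_bp <= 0:
            raise PipelineError("thresholds must be positive")
        if self.mendelian_policy not in ("error", "prior"):
            raise PipelineError("mendelian_policy must be 'error' or 'prior'")
        if self.assoc_region is not None:
            _parse_region(self.assoc_region)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "sample_sizes" in data:
            data["sample_sizes"] = tuple(data["sample_sizes"])
        return cls(**data)


def _parse_region(spec: str) -> tuple[str, int, int]:
    try:
        chrom, span = spec.split(":")
        start, end = (int(x) for x in span.split("-"))
    except ValueError as exc:
        raise PipelineError(f"bad region spec {spec!r}, want chr:start-end") from exc
    if start > end:
        raise PipelineError(f"region bounds out of order in {spec!r}")
    return chrom, start, end


def marker_ibd(
    ped,
    geno,
    maf: float,
    mc_samples: int,
    seed: int,
    mendelian_policy: str = "error",
    kin=None,
):
    """Per-pedigree IBD at a marker: exact, falling back to Monte-Carlo.

    Under ``mendelian_policy='prior'`` a Mendelian-inconsistent marker's Pi
    is blanked to the unconditional 2*Phi with a logged warning instead of
    raising.
    """
    try:
        return compute_ibd_exact(ped, geno, maf), None
    except IbdSizeError:
        pass
    except MendelianInconsistencyError:
        if mendelian_policy == "prior" and kin is not None:
            logger.warning(
                "marker %s family %s: Mendelian inconsistency; using prior 2*Phi",
                geno.marker_id, ped.family_id,
            )
            return prior_ibd(kin, geno.marker_id), "mendelian_prior"
        raise
    try:
        return compute_ibd_montecarlo(ped, geno, maf, mc_samples, seed), "mc"
    except MendelianInconsistencyError:
        if mendelian_policy == "prior" and kin is not None:
            return prior_ibd(kin, geno.marker_id), "mendelian_prior"
        raise


def run_multiphase(cfg: PipelineConfig) -> dict:
    """Execute the configured phases; returns (and writes) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: v for k, v in asdict(cfg).items()},
        "phases": {},
        "soft_failures": {},
    }

    peds = read_pedigree(cfg.ped_path)
    kin = {p.family_id: compute_kinship(p) for p in peds}
    fam_of = {m.individual_id: p.family_id for p in peds for m in p.members}
    manifest["n_pedigrees"] = len(peds)
    manifest["n_individuals"] = sum(len(p) for p in peds)

    # ---- phase 1: phenotype adjustment -----------------------------------
    R = None
    if cfg.run_adjust:
        records = read_exam_csv(cfg.pheno_path)
        fits = {}
        for exam in (1, 2, 3):
            sub = records[records["exam"] == exam]
            if len(sub) == 0:
                continue
            fit = fit_censored_exam(sub, fam_of)
            fits[exam] = fit
            (out / f"fit_exam{exam}.json").write_text(
                json.dumps(fit.report(), sort_keys=True, indent=1)
            )
        adjusted, skipped = build_adjusted_phenotype(fits, records, fam_of)
        adjusted.to_csv(out / "adjusted.csv", index=False, float_format="%.10g")
        R = adjusted.set_index("id")["R"]
        manifest["phases"]["adjust"] = {
            "n_adjusted": len(adjusted),
            "n_skipped": len(skipped),
            "skipped": skipped,
        }
    else:
        adj_path = out / "adjusted.csv"
        if not adj_path.exists():
            raise PipelineError("adjust phase disabled but no adjusted.csv present")
        R = pd.read_csv(adj_path, dtype={"id": str}).set_index("id")["R"]

    # ---- phase 2: linkage scan ------------------------------------------
    regions = []
    if cfg.run_linkage:
        markers = read_genotypes(cfg.gwas_geno_path, cfg.gwas_map_path)
        for m in markers:
            try:
                estimate_allele_freq(m, peds, method="founders_only")
            except AlleleFrequencyError:
                estimate_allele_freq(m, peds, method="all_counted")
        null = fit_polygenic_null(R, kin)
        manifest["phases"]["linkage"] = {
            "null": {
                "mu": null.mu,
                "sigma2_a": null.sigma2_a,
                "sigma2_e": null.sigma2_e,
                "h2": null.h2,
                "loglik": null.loglik,
            },
            "rounds": [],
        }
        all_fits = []
        excluded: set[str] = set()
        mend = 0
        for round_idx, n_sample in enumerate(cfg.sample_sizes):
            picked = sample_markers(
                markers, n_sample, cfg.maf_min, excluded,
                seed=phase_seed(cfg.seed, "sample_markers", round_idx),
            )
            excluded.update(m.marker_id for m in picked)
            for m in picked:
                ibd = {}
                for k, ped in enumerate(peds):
                    mat, note = marker_ibd(
                        ped, m, m.maf, cfg.ibd_mc_samples,
                        phase_seed(cfg.seed, "ibd", k),
                        cfg.mendelian_policy, kin[ped.family_id],
                    )
                    if note == "mendelian_prior":
                        mend += 1
                    ibd[ped.family_id] = mat
                all_fits.append(fit_vc_linkage(R, kin, ibd, null=null, marker=m))
            manifest["phases"]["linkage"]["rounds"].append(
                {"n_sampled": n_sample, "total_sampled": len(excluded)}
            )
        manifest["soft_failures"]["mendelian_prior_substitutions"] = mend
        fits_to_frame(all_fits).to_csv(
            out / "linkage.tsv", sep="\t", index=False, float_format="%.6g"
        )
        regions = select_regions(all_fits, cfg.lod_threshold, cfg.merge_bp)
        regions_to_frame(regions).to_csv(
            out / "regions.tsv", sep="\t", index=False, float_format="%.6g"
        )
        manifest["phases"]["linkage"]["n_regions"] = len(regions)

    # ---- phase 3: association ------------------------------------------
    if cfg.run_assoc:
        intervals: list[tuple[str, int, int]] = []
        if cfg.assoc_region is not None:
            intervals.append(_parse_region(cfg.assoc_region))
        intervals.extend((r.chromosome, r.start_bp, r.end_bp) for r in regions)
        if not intervals:
            manifest["phases"]["assoc"] = {
                "skipped": True,
                "reason": "no linkage region exceeded the LOD threshold and "
                          "no region override was given",
            }
        else:
            seq_path = cfg.seq_geno_path or cfg.gwas_geno_path
            seq_map = cfg.seq_map_path or cfg.gwas_map_path
            variants = read_genotypes(seq_path, seq_map)
            in_region = [
                v
                for v in variants
                if any(
                    v.chromosome == c and s <= v.position_bp <= e
                    for c, s, e in intervals
                )
            ]
            results = []
            failures = 0
            for k, v in enumerate(in_region):
                try:
                    estimate_allele_freq(v, peds, method="founders_only")
                except AlleleFrequencyError:
                    try:
                        estimate_allele_freq(v, peds, method="all_counted")
                    except AlleleFrequencyError:
                        failures += 1
                        continue
                ibd_opt = None
                if cfg.linkage_vc_in_assoc:
                    ibd_opt = {}
                    for j, ped in enumerate(peds):
                        mat, _ = marker_ibd(
                            ped, v, v.maf, cfg.ibd_mc_samples,
                            phase_seed(cfg.seed, "assoc", j),
                            cfg.mendelian_policy, kin[ped.family_id],
                        )
                        ibd_opt[ped.family_id] = mat
                res = analyze_marker(R, kin, v, peds, ibd_opt=ibd_opt)
                if not res.informative:
                    failures += 1
                results.append(res)
            results_to_frame(results).to_csv(
                out / "assoc.tsv", sep="\t", index=False, float_format="%.6g"
            )
            pvals = [r.p_mg for r in results if np.isfinite(r.p_mg)]
            qq = None
            if len(pvals) >= 100:
                d = qq_diagnostics(pvals)
                qq = {"lambda": d["lambda"], "n": d["n"],
                      "deflated": d["deflated"], "inflated": d["inflated"]}
            manifest["phases"]["assoc"] = {
                "intervals": [list(i) for i in intervals],
                "n_variants_in_region": len(in_region),
                "n_tested": len(results),
                "n_flagged": failures,
                "qq_mg": qq,
            }

    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1, default=str)
    )
    return manifest
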