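"""End-to-end run orchestration: simulate -> gpa -> pca -> brim -> fscp -> stats.

Each stage writes versioned outputs into the run directory plus a
machine-readable manifest (inputs, options, seeds, file hashes) and a human
log.  A stage whose outputs already exist is skipped, so deleting
downstream outputs and re-running resumes from the last valid stage.  No
stage mutates its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as fio
from .brim import BRIMConfig, PredictorVariable, rip_effect_maps, run_brim, run_partial_brim
from .fscp import compare_surfaces, permutation_significance
from .morphometry import (
    fit_shape_pca,
    generalized_procrustes,
    project_tangent,
    scores,
    symmetric_components,
)
from .simulate import CohortConfig, simulate_cohort
from .stats import genotype_anova, roc_auc

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("facebrim")


@dataclass
class RunConfig:
    """Options for one pipeline run (echoed verbatim to the manifest)."""

    output_dir: str = "facebrim_run"
    # either simulate a cohort ...
    cohort: CohortConfig | None = None
    # ... or point at existing inputs
    mask_path: str | None = None
    landmarks_path: str | None = None
    covariates_path: str | None = None
    genotypes_path: str | None = None
    # morphometry
    retained_fraction: float = 0.98
    tangent: bool = True
    # brim
    brim: BRIMConfig = field(default_factory=BRIMConfig)
    # fscp
    permutations: int = 999
    alpha: float = 0.001
    k_sd: float = 3.0
    seed: int = 0


def _hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_done(outdir: Path, names) -> bool:
    return all((outdir / n).exists() for n in names)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the pipeline; returns the run directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest_path = outdir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest["options"] = json.loads(json.dumps(asdict(config), default=str))
    t0 = time.time()

    def record(stage, outputs):
        manifest.setdefault("stages", {})[stage] = {
            "outputs": {n: _hash(outdir / n) for n in outputs},
            "elapsed_s": round(time.time() - t0, 2),
        }
        manifest_path.write_text(json.dumps(manifest, indent=1))
        log.info("stage %s done (%s)", stage, ", ".join(outputs))

    try:
        # --- stage: simulate (or load) ------------------------------------
        sim_outputs = ["mask.json", "landmarks.csv", "covariates.csv", "genotypes.csv"]
        if config.cohort is not None:
            if not _stage_done(outdir, sim_outputs):
                cohort = simulate_cohort(config.cohort)
                fio.write_mask(cohort.mask, outdir / "mask.json")
                fio.write_landmark_table(
                    cohort.configurations, cohort.ids, outdir / "landmarks.csv"
                )
                fio.write_covariates(
                    outdir / "covariates.csv",
                    cohort.ids,
                    cohort.sex,
                    q_true=cohort.ancestry_true,
                    ancestry_estimate=cohort.ancestry_true,
                )
                fio.write_genotypes(
                    outdir / "genotypes.csv", cohort.ids, cohort.genotypes
                )
                record("simulate", sim_outputs)
            mask_path = outdir / "mask.json"
            landmarks_path = outdir / "landmarks.csv"
            covariates_path = outdir / "covariates.csv"
            genotypes_path = outdir / "genotypes.csv"
        else:
            for p, what in [
                (config.mask_path, "mask"),
                (config.landmarks_path, "landmarks"),
                (config.covariates_path, "covariates"),
            ]:
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{what} input missing: {p}")
            mask_path = Path(config.mask_path)
            landmarks_path = Path(config.landmarks_path)
            covariates_path = Path(config.covariates_path)
            genotypes_path = (
                Path(config.genotypes_path) if config.genotypes_path else None
            )

        mask = fio.read_mask(mask_path)
        configs, ids = fio.read_landmark_table(landmarks_path, mask)
        cov = fio.read_covariates(covariates_path)

        # --- stage: gpa ----------------------------------------------------
        if not _stage_done(outdir, ["aligned.npz"]):
            sample = generalized_procrustes(configs, mask, include_reflections=True)
            if config.tangent:
                sample = project_tangent(sample)
            np.savez_compressed(
                outdir / "aligned.npz",
                shapes=sample.shapes,
                consensus=sample.consensus,
                centroid_sizes=sample.centroid_sizes,
                n_original=sample.n_original,
                tangent=config.tangent,
            )
            record("gpa", ["aligned.npz"])
        with np.load(outdir / "aligned.npz") as d:
            from .morphometry import AlignedSample

            sample = AlignedSample(
                shapes=d["shapes"],
                consensus=d["consensus"],
                centroid_sizes=d["centroid_sizes"],
                n_original=int(d["n_original"]),
                includes_reflections=True,
                tangent_projected=bool(d["tangent"]),
            )
        sym, _asym = symmetric_components(sample)

        # --- stage: pca ----------------------------------------------------
        if not _stage_done(outdir, ["shape_space.npz", "pc_scores.csv"]):
            space = fit_shape_pca(sym, config.retained_fraction, center=sample.consensus)
            fio.save_shape_space(space, outdir / "shape_space.npz")
            sc = scores(space, sym)
            import pandas as pd

            pd.DataFrame(
                sc, columns=[f"PC{i + 1}" for i in range(sc.shape[1])]
            ).assign(id=ids).to_csv(outdir / "pc_scores.csv", index=False)
            record("pca", ["shape_space.npz", "pc_scores.csv"])
        space = fio.load_shape_space(outdir / "shape_space.npz")
        responses = scores(space, sym)

        # --- stage: brim ----------------------------------------------------
        if not _stage_done(outdir, ["rip.csv"]):
            import pandas as pd

            anc_col = (
                "ancestry_estimate" if "ancestry_estimate" in cov.columns else "q_true"
            )
            rip_a = run_brim(
                PredictorVariable(cov[anc_col].to_numpy(), "continuous", "A"),
                responses,
                config=config.brim,
            )
            rip_s = run_brim(
                PredictorVariable(cov["sex"].to_numpy().astype(float), "binary", "S"),
                responses,
                config=config.brim,
            )
            out = pd.DataFrame({"id": ids, "RIP-A": rip_a.rip, "RIP-S": rip_s.rip})
            rip_g = {}
            if genotypes_path is not None and Path(genotypes_path).exists():
                geno = fio.read_genotypes(genotypes_path)
                for snp in geno.columns[1:]:
                    res = run_partial_brim(
                        PredictorVariable(
                            geno[snp].to_numpy(dtype=float), "genotype", snp
                        ),
                        responses,
                        rip_a,
                        rip_s,
                        config=config.brim,
                    )
                    rip_g[snp] = res.rip
                    out[f"RIP-G:{snp}"] = res.rip
            out.to_csv(outdir / "rip.csv", index=False, float_format="%.9g")
            np.savez_compressed(
                outdir / "brim_trace.npz",
                rip_a=rip_a.per_iteration,
                rip_s=rip_s.per_iteration,
                rip_a_convergence=rip_a.convergence_trace,
                rip_s_convergence=rip_s.convergence_trace,
            )
            record("brim", ["rip.csv"])
        import pandas as pd

        rips = pd.read_csv(outdir / "rip.csv")

        # --- stage: fscp ----------------------------------------------------
        if not _stage_done(outdir, ["fscp_maps.csv"]):
            rows = []
            for col in [c for c in rips.columns if c != "id"]:
                maps = rip_effect_maps(
                    rips[col].to_numpy(), sym, center=space.mean, k=config.k_sd
                )
                surf = compare_surfaces(maps.shape_minus, maps.shape_plus, mask)
                p, sig = permutation_significance(
                    rips[col].to_numpy(),
                    sym,
                    B=config.permutations,
                    alpha=config.alpha,
                    seed=config.seed,
                )
                for l in range(mask.n_landmarks):
                    rows.append(
                        {
                            "variable": col,
                            "landmark": l,
                            "r2": maps.r2[l],
                            "area_ratio": surf.area_ratio[l],
                            "curvature_difference": surf.curvature_difference[l],
                            "normal_displacement": surf.normal_displacement[l],
                            "p": p[l],
                            "significant": bool(sig[l]),
                        }
                    )
            pd.DataFrame(rows).to_csv(outdir / "fscp_maps.csv", index=False)
            record("fscp", ["fscp_maps.csv"])

        # --- stage: stats ----------------------------------------------------
        if not _stage_done(outdir, ["stats.csv"]):
            rows = []
            if "sex" in cov.columns and "RIP-S" in rips.columns:
                auc, _ = roc_auc(rips["RIP-S"].to_numpy(), cov["sex"].to_numpy())
                rows.append({"test": "roc_auc_sex", "statistic": auc, "p": None})
            if "q_true" in cov.columns and "RIP-A" in rips.columns:
                r = float(
                    np.corrcoef(rips["RIP-A"].to_numpy(), cov["q_true"].to_numpy())[0, 1]
                )
                rows.append({"test": "corr_ripa_ancestry", "statistic": r, "p": None})
            if genotypes_path is not None and Path(genotypes_path).exists():
                geno = fio.read_genotypes(genotypes_path)
                for snp in geno.columns[1:]:
                    col = f"RIP-G:{snp}"
                    if col in rips.columns:
                        res = genotype_anova(
                            rips[col].to_numpy(), geno[snp].to_numpy(dtype=float)
                        )
                        rows.append(
                            {"test": f"anova_{snp}", "statistic": res.f_statistic,
                             "p": res.p_value}
                        )
            pd.DataFrame(rows).to_csv(outdir / "stats.csv", index=False)
            record("stats", ["stats.csv"])
    except Exception as exc:  # halt with stage context in the log
        log.error("pipeline halted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
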