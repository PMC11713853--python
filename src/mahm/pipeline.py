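"""End-to-end pipeline and synthetic cohort studies.

`run_pipeline` ties the modules together for the command line: read or
simulate a hybrid stack, harmonize the grid, compute eigen-maps and
conventional ADC/T2 maps, render display images, summarize ROIs and write a
stats report with full provenance.

The cohort helpers emulate the paired study design: n patients, each with
one cancer and one normal-tissue ROI, summarized per case and compared with
the Wilcoxon signed-rank test and ROC analysis.  Patients differ by
tissue-composition jitter, amplitude jitter and independent noise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

import mahm
from mahm import io as mio
from mahm.core import compute_eigenmaps, harmonize_grid
from mahm.grid import AcquisitionGrid, HybridStack
from mahm.phantom import (
    PhantomSpec,
    default_profiles,
    make_phantom,
    two_region_spec,
)
from mahm.relaxometry import parametric_maps
from mahm.rendering import (
    colorize,
    eigenvalue_scaling,
    eigenvector_scaling,
    merge_rgb,
    overlay,
    scale_to_8bit,
)
from mahm.stats import combined_auc, roc_auc, roi_summary, wilcoxon_signed_rank

__all__ = [
    "RunConfig",
    "run_pipeline",
    "case_features",
    "simulate_cohort",
    "cohort_analysis",
    "wilcoxon_power",
]

FEATURES = ("lambda_r", "adc", "t2")


# ---------------------------------------------------------------------------
# cohort simulation

#: Standard deviation of the per-patient volume-fraction jitter.
FRACTION_JITTER_SD = 0.04
#: Log-amplitude jitter between patients (scanner gain / coil loading).
AMPLITUDE_JITTER_SD = 0.10


def _jitter_profile(profile, rng, sd=FRACTION_JITTER_SD):
    frac = np.array([c.volume_fraction for c in profile.compartments])
    frac = np.clip(frac + rng.normal(0.0, sd, len(frac)), 0.02, None)
    frac /= frac.sum()
    amp = profile.base_amplitude * float(np.exp(rng.normal(0, AMPLITUDE_JITTER_SD)))
    return replace(profile.with_fractions(frac), base_amplitude=amp)


def case_features(
    spec: PhantomSpec,
    target_m: int = 3,
    target_n: int = 3,
) -> dict[str, float]:
    """Per-case ROI feature summaries from one phantom 'patient'.

    The phantom is harmonized to ``target_m`` x ``target_n``, eigen-maps
    and relaxometry maps are computed, and each ROI is summarized by its
    median: lambda_r (capped pixels excluded), ADC at the shortest TE
    (mm^2/s) and T2 at b = 0 (ms).
    """
    stack, _, masks = make_phantom(spec)
    stack = harmonize_grid(stack, target_m, target_n)
    tissue = np.zeros(stack.spatial_shape, dtype=bool)
    for m in masks.values():
        tissue |= m
    emaps = compute_eigenmaps(stack, tissue)
    pmaps = parametric_maps(stack, tissue)
    out: dict[str, float] = {}
    for name, mask in masks.items():
        tag = "cancer" if name == "cancer" else "normal"
        out[f"lambda_r_{tag}"] = roi_summary(
            emaps.lambda_r, mask, exclude_flagged=emaps.capped
        )
        out[f"adc_{tag}"] = roi_summary(pmaps.adc[..., 0], mask)
        out[f"t2_{tag}"] = roi_summary(pmaps.t2[..., 0], mask)
    return out


def simulate_cohort(
    n_cases: int = 18,
    seed: int = 0,
    shape: tuple[int, int] = (16, 16),
    roi_size: int = 5,
    snr: Optional[float] = 50.0,
    grid: Optional[AcquisitionGrid] = None,
    target_m: int = 3,
    target_n: int = 3,
) -> pd.DataFrame:
    """Simulate a paired cohort: one row per patient with
    ``<feature>_cancer`` / ``<feature>_normal`` columns.

    Each patient draws jittered tissue profiles (compartment fractions and
    base amplitude) and an independent noise realization, all derived
    deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for child in ss.spawn(n_cases):
        rng = np.random.default_rng(child)
        base = default_profiles()
        profs = {name: _jitter_profile(p, rng) for name, p in base.items()}
        noise_seed = int(rng.integers(0, 2**31 - 1))
        spec = two_region_spec(
            shape=shape,
            roi_size=roi_size,
            snr=snr,
            seed=noise_seed,
            grid=grid,
            profiles=profs,
        )
        rows.append(case_features(spec, target_m, target_n))
    return pd.DataFrame(rows)


def cohort_analysis(table: pd.DataFrame) -> dict:
    """Paired Wilcoxon tests and ROC AUCs for a cohort feature table.

    ROC analysis pools the cancer and normal ROI summaries (labels 1/0,
    two observations per case); the combined AUC uses a logistic
    combination of all three features.
    """
    report: dict = {"n_cases": int(len(table)), "features": {}}
    labels = np.r_[np.ones(len(table)), np.zeros(len(table))]
    pooled = {}
    for feat in FEATURES:
        cancer = table[f"{feat}_cancer"].to_numpy()
        normal = table[f"{feat}_normal"].to_numpy()
        stat, p = wilcoxon_signed_rank(np.c_[cancer, normal])
        scores = np.r_[cancer, normal]
        roc = roc_auc(scores, labels)
        pooled[feat] = scores
        report["features"][feat] = {
            "wilcoxon_statistic": stat,
            "wilcoxon_p": p,
            "auc": roc.auc,
            "direction": roc.direction,
            "median_cancer": float(np.median(cancer)),
            "median_normal": float(np.median(normal)),
        }
    X = np.column_stack([pooled[f] for f in FEATURES])
    roc_comb, _ = combined_auc(X, labels, feature_names=list(FEATURES))
    report["combined_auc"] = roc_comb.auc
    return report


def wilcoxon_power(
    feature: str,
    n_replicates: int = 200,
    n_cases: int = 18,
    seed: int = 0,
    alpha: float = 0.05,
    **cohort_kwargs,
) -> float:
    """Fraction of seeded cohort replicates where the paired Wilcoxon test
    on ``feature`` rejects at level ``alpha``."""
    rejections = 0
    for r in range(n_replicates):
        table = simulate_cohort(n_cases=n_cases, seed=seed + 10_000 * (r + 1),
                                **cohort_kwargs)
        _, p = wilcoxon_signed_rank(
            np.c_[table[f"{feature}_cancer"], table[f"{feature}_normal"]]
        )
        rejections += p < alpha
    return rejections / n_replicates


# ---------------------------------------------------------------------------
# file pipeline


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    out_dir: str
    volume: Optional[str] = None
    sidecar: Optional[str] = None
    simulate: bool = False
    shape: tuple[int, int] = (24, 24)
    roi_size: int = 6
    snr: Optional[float] = 50.0
    seed: int = 0
    target_m: Optional[int] = 3
    target_n: Optional[int] = 3
    keep_tes: Optional[Sequence[float]] = None
    keep_bs: Optional[Sequence[float]] = None
    rel_floor: float = 1e-6
    lambda_r_cap: Optional[float] = None
    render: bool = True
    mask_paths: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate/read -> harmonize -> eigen-maps -> relaxometry ->
    render -> ROI stats, writing everything under ``config.out_dir``.

    Returns the provenance/report dictionary (also written as
    ``report.json``).  Deterministic under a fixed seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        if config.simulate:
            spec = two_region_spec(
                shape=tuple(config.shape),
                roi_size=config.roi_size,
                snr=config.snr,
                seed=config.seed,
            )
            stack, labels, masks = make_phantom(spec)
            mio.write_stack(stack, out / "phantom.nii", out / "phantom.json")
            mio.write_mask(labels, out / "labels.nii")
            for name, m in masks.items():
                mio.write_mask(m, out / f"mask_{name}.nii")
        else:
            if not (config.volume and config.sidecar):
                raise ValueError(
                    "either simulate=True or volume+sidecar paths are required"
                )
            stack = mio.read_stack(config.volume, config.sidecar)
            masks = {
                name: mio.read_mask(p) for name, p in config.mask_paths.items()
            }

        stage = "harmonize"
        harmonized = stack
        if config.target_m is not None and config.target_n is not None:
            harmonized = harmonize_grid(
                stack, config.target_m, config.target_n,
                config.keep_tes, config.keep_bs,
            )

        stage = "eigenmaps"
        valid = np.any(harmonized.signal > 0, axis=(3, 4))
        emaps = compute_eigenmaps(
            harmonized, valid, rel_floor=config.rel_floor,
            cap=config.lambda_r_cap,
        )
        mio.write_eigenmaps(emaps, out)
        mio.eigenmaps_to_frame(emaps).to_csv(out / "pixels.csv", index=False)

        stage = "relaxometry"
        pmaps = parametric_maps(harmonized, valid, rel_floor=config.rel_floor)
        mio.write_map(
            pmaps.adc, out / "adc.nii", units="mm^2/s",
            sidecar_path=out / "adc.json", axis4="per-TE",
            tes_ms=list(pmaps.tes),
        )
        mio.write_map(
            pmaps.t2, out / "t2.nii", units="ms",
            sidecar_path=out / "t2.json", axis4="per-b",
            bvalues_s_mm2=list(pmaps.bvalues),
        )

        stage = "render"
        if config.render:
            _render_outputs(harmonized, emaps, valid, out)

        stage = "stats"
        stats_report = {}
        roi_masks = {k: v for k, v in masks.items()} if masks else {}
        if roi_masks:
            adc0 = pmaps.adc[..., 0]
            t2_b0 = pmaps.t2[..., 0]
            for name, m in roi_masks.items():
                stats_report[name] = {
                    "lambda_r": roi_summary(
                        emaps.lambda_r, m, exclude_flagged=emaps.capped
                    ),
                    "adc": roi_summary(adc0, m),
                    "t2": roi_summary(t2_b0, m),
                    "n_pixels": int(m.sum()),
                }
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    report = {
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "seed": config.seed,
        "versions": {"mahm": mahm.__version__, "numpy": np.__version__},
        "grid": {
            "tes_ms": list(harmonized.grid.tes),
            "bvalues_s_mm2": list(harmonized.grid.bvalues),
            "original_tes_ms": list(stack.grid.tes),
            "original_bvalues_s_mm2": list(stack.grid.bvalues),
        },
        "orientation": emaps.orientation,
        "lambda_r_cap": emaps.cap,
        "roi_stats": stats_report,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _render_outputs(stack: HybridStack, emaps, valid, out: Path) -> None:
    """PNG renders for the middle slice: merged RGB eigenvalue map,
    eigenvector component maps and the rainbow lambda_r overlay."""
    z = stack.spatial_shape[2] // 2
    base = stack.signal[:, :, z, 0, 0]
    vmask = valid[:, :, z]
    if not vmask.any():
        raise ValueError(
            "no valid pixels in the display slice; eigenvalue-mode "
            "rendering needs a non-empty mask"
        )
    channels = []
    bounds = {}
    for i in range(min(emaps.k, 3)):
        lam = emaps.eigenvalues[:, :, z, i]
        sc = eigenvalue_scaling(lam, vmask)
        channels.append(scale_to_8bit(lam, sc))
        bounds[f"lambda{i + 1}"] = {"vmin": sc.vmin, "vmax": sc.vmax}
    rgb = merge_rgb(*channels)
    mio.write_png(
        overlay(base, rgb, vmask), out / "eigenvalue_rgb.png",
        scaling_meta=bounds,
    )
    vsc = eigenvector_scaling()
    for i in range(min(emaps.k, 3)):
        comp = scale_to_8bit(emaps.eigenvectors[:, :, z, :, i][..., 0], vsc)
        mio.write_png(comp, out / f"eigenvector_e{i + 1}1.png")
    lr = emaps.lambda_r[:, :, z]
    lr_rgb = colorize(lr, 0.0, emaps.cap)
    mio.write_png(
        overlay(base, lr_rgb, vmask), out / "lambda_r_overlay.png",
        scaling_meta={"vmin": 0.0, "vmax": emaps.cap, "cmap": "turbo"},
    )
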