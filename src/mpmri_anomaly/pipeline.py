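"""End-to-end orchestration.

One config drives the whole workflow: phantom (or NIfTI) input -> stitched
hypercube -> background statistics under each requested conditioning method
-> RX maps -> reference masks (thresholded ACE, CIELAB yellowness, or
phantom truth) -> per-case ROC curves -> cohort summary tables laid out as
references x methods.  Identical config and seed reproduce every output
byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import background, colorref, detect, evaluate, hypercube, phantom

log = logging.getLogger("mpmri_anomaly")

METHODS = (
    "delete_pc_3",
    "delete_pc_4",
    "modified_regularized",
    "regularized",
    "evm",
    "unprocessed",
)
REFERENCES = ("ace", "cielab", "truth")


@dataclass
class RunConfig:
    methods: tuple[str, ...] = METHODS
    references: tuple[str, ...] = ("ace", "cielab")
    n_cases: int = 4
    ace_threshold: float = colorref.ACE_THRESHOLD
    cielab_threshold: float = colorref.CIELAB_THRESHOLD
    seed: int = 0
    out_dir: str = "run_out"
    # phantom generation knobs (ignored when nifti_cases is given)
    grid_shape: tuple[int, int] = (64, 64)
    n_slices: int = 3
    tumor_mahalanobis: float = 4.5
    outlier_fraction: float = 0.0
    #: statistics mask: exclude the truth tumor region when available
    exclude_tumor_from_stats: bool = True
    save_maps: bool = True
    #: optional real-data input: list of {"cube": path, "prostate_mask": path,
    #: "tumor_mask": optional path} dicts
    nifti_cases: list[dict] | None = None

    def validate(self) -> None:
        if not self.methods or not self.references:
            raise ValueError("need at least one method and one reference")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
        for r in self.references:
            if r not in REFERENCES:
                raise ValueError(f"unknown reference {r!r}; choose from {REFERENCES}")
        if not (0 < self.ace_threshold < 1 and 0 < self.cielab_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.n_cases < 2:
            raise ValueError("need >= 2 cases for cohort standard errors")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        for key in ("methods", "references", "grid_shape"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class CaseResult:
    case_id: int
    roc: dict[tuple[str, str], evaluate.ROCResult]  # (method, reference) -> ROC


@dataclass
class RunReport:
    config: RunConfig
    cases: list[CaseResult]
    summaries: dict[tuple[str, str], evaluate.CohortSummary]
    auc_table: pd.DataFrame  # rows = references, cols = methods
    yi_table: pd.DataFrame
    out_dir: Path


def _load_case(cfg: RunConfig, i: int, case_seed: int):
    """Returns (cube, masks) with masks containing prostate/tumor/outlier."""
    if cfg.nifti_cases is not None:
        entry = cfg.nifti_cases[i]
        cube = hypercube.load_cube_nifti(entry["cube"])
        masks = {"prostate": hypercube.load_mask_nifti(entry["prostate_mask"])}
        if "tumor_mask" in entry and entry["tumor_mask"]:
            masks["tumor"] = hypercube.load_mask_nifti(entry["tumor_mask"])
        return cube, masks
    spec = phantom.default_spec(
        seed=case_seed,
        grid_shape=cfg.grid_shape,
        n_slices=cfg.n_slices,
        tumor_mahalanobis=cfg.tumor_mahalanobis,
        outlier_fraction=cfg.outlier_fraction,
    )
    slices, truth = phantom.generate_phantom(spec)
    cube, masks = hypercube.stitch_cubes(
        slices,
        masks={
            "prostate": list(truth.prostate_mask),
            "tumor": list(truth.tumor_mask),
            "outlier": list(truth.outlier_mask),
        },
        channel_names=spec.channel_names,
    )
    return cube, masks


def run_case(cfg: RunConfig, i: int, case_seed: int) -> tuple[CaseResult, dict]:
    """Process one case; returns the ROC grid plus artifacts for persistence."""
    cube, masks = _load_case(cfg, i, case_seed)
    prostate = masks["prostate"]
    cube.validate_finite(prostate)
    tumor = masks.get("tumor")
    if cfg.exclude_tumor_from_stats and tumor is not None:
        normal_mask = prostate & ~tumor
    else:
        normal_mask = prostate
    log.info("case %d: %d prostate voxels, %d used for statistics",
             i, int(prostate.sum()), int(normal_mask.sum()))

    # references -----------------------------------------------------------
    refs: dict[str, np.ndarray] = {}
    artifacts: dict[str, np.ndarray] = {}
    if "ace" in cfg.references:
        if tumor is None:
            raise ValueError(
                f"case {i}: ACE reference needs a tumor seed region "
                "(tumor_mask) for the in-scene signature"
            )
        sig = detect.extract_signature(cube, tumor)
        base = background.condition_unprocessed(
            background.compute_stats(cube, normal_mask)
        )
        amap = detect.ace_map(cube, base, sig, prostate)
        refs["ace"] = colorref.ace_reference(amap, prostate, cfg.ace_threshold)
        artifacts["ace_scores"] = amap.scores
    if "cielab" in cfg.references:
        rgb, rgb_flags = colorref.compose_rgb(cube, colorref.ChannelColorMap(), prostate)
        lab = colorref.rgb_to_lab(rgb)
        refs["cielab"] = colorref.yellow_mask(lab, prostate, cfg.cielab_threshold)
        artifacts["rgb"] = rgb
        if rgb_flags:
            log.warning("case %d: %s", i, "; ".join(rgb_flags))
    if "truth" in cfg.references:
        if tumor is None:
            raise ValueError(f"case {i}: truth reference requires a tumor mask")
        refs["truth"] = tumor & prostate

    # conditioning + RX ----------------------------------------------------
    roc: dict[tuple[str, str], evaluate.ROCResult] = {}
    for method in cfg.methods:
        try:
            cs = background.condition(cube, normal_mask, method, seed=case_seed)
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise RuntimeError(
                f"stage 'condition:{method}' failed on case {i}: {exc}"
            ) from exc
        if cs.eigenvalues is not None:
            log.info("case %d %s: eigenvalues %s params %s", i, method,
                     np.array2string(cs.eigenvalues, precision=3),
                     {k: v for k, v in cs.params.items()
                      if not isinstance(v, np.ndarray)})
        rmap = detect.rx_map(cube, cs, prostate)
        artifacts[f"rx_{method}"] = rmap.scores
        for ref_name, ref in refs.items():
            try:
                roc[(method, ref_name)] = evaluate.roc_curve(rmap, ref, prostate)
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(
                    f"stage 'roc:{method}/{ref_name}' failed on case {i}: {exc}"
                ) from exc
    for name, ref in refs.items():
        artifacts[f"reference_{name}"] = ref
    artifacts["prostate_mask"] = prostate
    return CaseResult(case_id=i, roc=roc), artifacts


def run(cfg: RunConfig) -> RunReport:
    """Execute the configured grid over all cases and write every artifact."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    case_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(cfg.seed).spawn(cfg.n_cases)
    ]
    cases: list[CaseResult] = []
    for i, cseed in enumerate(case_seeds):
        case, artifacts = run_case(cfg, i, cseed)
        cases.append(case)
        cdir = out / f"case_{i:03d}"
        cdir.mkdir(exist_ok=True)
        for (method, ref), r in case.roc.items():
            pd.DataFrame(
                evaluate.roc_to_table(r),
                columns=["threshold", "sensitivity", "one_minus_specificity"],
            ).to_csv(cdir / f"roc_{method}_{ref}.csv", index=False)
        if cfg.save_maps:
            for name, arr in artifacts.items():
                if arr.ndim == 2:
                    hypercube.save_image_nifti(cdir / f"{name}.nii.gz", arr)

    summaries = {
        (m, r): evaluate.cohort_summary([c.roc[(m, r)] for c in cases])
        for m in cfg.methods
        for r in cfg.references
    }
    auc_table = pd.DataFrame(
        {m: [summaries[(m, r)].mean_auc for r in cfg.references] for m in cfg.methods},
        index=list(cfg.references),
    )
    yi_table = pd.DataFrame(
        {m: [summaries[(m, r)].mean_yi for r in cfg.references] for m in cfg.methods},
        index=list(cfg.references),
    )
    auc_table.to_csv(out / "summary_auc.csv", float_format="%.6f")
    yi_table.to_csv(out / "summary_yi.csv", float_format="%.6f")
    long = pd.DataFrame(
        [
            {
                "method": m,
                "reference": r,
                "mean_auc": s.mean_auc,
                "se_auc": s.se_auc,
                "mean_yi": s.mean_yi,
                "se_yi": s.se_yi,
                "n_cases": s.n,
            }
            for (m, r), s in summaries.items()
        ]
    )
    long.to_csv(out / "summary_long.csv", index=False, float_format="%.6f")
    manifest = {
        "config": json.loads(cfg.to_json()),
        "case_seeds": case_seeds,
        "n_cases": cfg.n_cases,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return RunReport(
        config=cfg,
        cases=cases,
        summaries=summaries,
        auc_table=auc_table,
        yi_table=yi_table,
        out_dir=out,
    )
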