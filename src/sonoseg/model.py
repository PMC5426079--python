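"""End-to-end model interface: fit a segmentation to one ultrasound image.

``SegmentationModel`` holds the data (full frame, ROI, optional truth mask)
and configuration; ``fit()`` runs the whole pipeline — crop and enhance the
tumor-centered image, tune the graph segmenter's (k, alpha) by particle
swarm under the three-term objective, re-segment at the optimum, clean the
reference region morphologically — and returns a ``SegmentationResult``
carrying the parameter estimates, the optimization trace, the objective
breakdown, the final mask/contour and (when truth is given) the metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .config import PipelineConfig
from .graph import RegionPartition
from .metrics import MetricsReport, evaluate_masks
from .objective import (
    NormalizationFactors,
    ObjectiveBreakdown,
    ObjectiveEvaluator,
    combined_objective,
    extract_reference_region,
)
from .postprocess import (
    extract_contour,
    largest_central_component,
    morph_open_close,
    to_binary,
)
from .preprocess import RoiRect, preprocess_pipeline, to_gray_u8
from .pso import OptimizationTrace, optimize


class DegenerateSegmentationError(RuntimeError):
    """The optimized segmentation produced an empty final mask."""


@dataclass
class SegmentationResult:
    """Fitted segmentation: estimates, diagnostics and artifacts."""

    k: float
    alpha: float
    tci: np.ndarray = field(repr=False)
    partition: RegionPartition = field(repr=False)
    mask: np.ndarray = field(repr=False)            # TCI coordinates, uint8 0/1
    contour: np.ndarray = field(repr=False)         # TCI coordinates (row, col)
    contour_fullframe: np.ndarray = field(repr=False)
    breakdown: ObjectiveBreakdown
    factors: NormalizationFactors
    trace: OptimizationTrace = field(repr=False)
    roi: RoiRect
    config: PipelineConfig = field(repr=False)
    n_evaluations: int = 0
    metrics: MetricsReport | None = None

    @property
    def n_generations(self) -> int:
        return len(self.trace.records) - 1

    def summary(self) -> str:
        b = self.breakdown
        lines = [
            "PSO-tuned graph segmentation",
            "=" * 46,
            f"{'optimal k':<28}{self.k:14.3f}",
            f"{'optimal alpha':<28}{self.alpha:14.4f}",
            f"{'generations':<28}{self.n_generations:14d}",
            f"{'fitness evaluations':<28}{self.n_evaluations:14d}",
            f"{'objective F_O':<28}{b.f_o:14.4f}",
            f"{'  between-class V_B':<28}{b.v_b:14.4f}",
            f"{'  within-class V_W':<28}{b.v_w:14.4f}",
            f"{'  boundary gradient G_A':<28}{b.g_a:14.4f}",
            f"{'norm factors f_B/f_W/f_A':<28}"
            f"{self.factors.f_b:10.2f}{self.factors.f_w:10.2f}{self.factors.f_a:10.2f}",
            f"{'regions at optimum':<28}{self.partition.n_regions:14d}",
            f"{'mask area (px)':<28}{int(self.mask.sum()):14d}",
        ]
        if self.metrics is not None:
            m = self.metrics
            lines += [
                "-" * 46,
                f"{'ARE (%)':<28}{m.are:14.2f}",
                f"{'TPVF (%)':<28}{m.tpvf:14.2f}",
                f"{'FPVF (%)':<28}{m.fpvf:14.2f}",
                f"{'FNVF (%)':<28}{m.fnvf:14.2f}",
            ]
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write mask/overlay PNGs, contour and trace CSVs, report JSON."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_mask(out / "mask.png", self.mask)
        _io.write_gray(out / "tci.png", self.tci)
        _io.write_overlay(out / "overlay.png", self.tci, self.contour)
        pd.DataFrame(
            {"x": self.contour[:, 1], "y": self.contour[:, 0]}
        ).to_csv(out / "contour.csv", index=False)
        self.trace.to_dataframe().to_csv(out / "trace.csv", index=False)
        report = {
            "k": self.k,
            "alpha": self.alpha,
            "objective": {
                "f_o": self.breakdown.f_o,
                "v_b": self.breakdown.v_b,
                "v_w": self.breakdown.v_w,
                "g_a": self.breakdown.g_a,
                "f_B": self.factors.f_b,
                "f_W": self.factors.f_w,
                "f_A": self.factors.f_a,
            },
            "roi": [self.roi.x0, self.roi.y0, self.roi.x1, self.roi.y1],
            "generations": self.n_generations,
            "evaluations": self.n_evaluations,
        }
        if self.metrics is not None:
            report["metrics"] = self.metrics.to_dict()
        (out / "report.json").write_text(json.dumps(report, indent=2))


class SegmentationModel:
    """The pipeline bound to one image.

    Parameters
    ----------
    image : 2-D (or RGB) array, the full ultrasound frame.
    roi : RoiRect or None; None takes the whole frame as the TCI.
    truth : optional ground-truth mask in full-frame coordinates; metrics
        are computed in TCI coordinates after cropping with the same ROI.
    config : PipelineConfig; defaults reproduce the published constants.
    """

    def __init__(
        self,
        image: np.ndarray,
        roi: RoiRect | None = None,
        truth: np.ndarray | None = None,
        config: PipelineConfig | None = None,
    ) -> None:
        self.image = to_gray_u8(image)
        h, w = self.image.shape
        self.roi = roi or RoiRect(0, 0, w, h)
        if truth is not None:
            truth = np.asarray(truth).astype(bool).astype(np.uint8)
            if truth.shape != self.image.shape:
                raise ValueError("truth mask must match the full frame shape")
        self.truth = truth
        self.config = config or PipelineConfig()
        th, tw = self.roi.shape
        if th < 8 or tw < 8:
            raise ValueError("TCI must be at least 8x8 pixels")

    @classmethod
    def from_files(
        cls,
        image_path: str | Path,
        roi: RoiRect | None = None,
        truth_path: str | Path | None = None,
        config: PipelineConfig | None = None,
    ) -> "SegmentationModel":
        image = _io.read_gray(image_path)
        truth = _io.read_mask(truth_path) if truth_path else None
        return cls(image, roi=roi, truth=truth, config=config)

    def fit(self) -> SegmentationResult:
        cfg = self.config
        tci = preprocess_pipeline(self.image, self.roi, cfg.preprocess)

        evaluator = ObjectiveEvaluator(
            tci, weights=cfg.weights, connectivity=cfg.connectivity,
            vw_form=cfg.vw_form,
        )
        p_g, trace = optimize(
            evaluator, cfg.pso, on_init=evaluator.set_normalization
        )
        k_opt, alpha_opt = float(p_g[0]), float(p_g[1])

        partition = evaluator.partition(k_opt, alpha_opt)
        ref = extract_reference_region(partition)
        raw = evaluator.breakdown(k_opt, alpha_opt)
        breakdown = ObjectiveBreakdown(
            v_b=raw.v_b, v_w=raw.v_w, g_a=raw.g_a,
            f_o=combined_objective(raw.v_b, raw.v_w, raw.g_a,
                                   evaluator.factors, cfg.weights),
        )

        mask = to_binary(partition, ref)
        if cfg.apply_morphology:
            mask = morph_open_close(mask)
        if cfg.keep_central_component:
            mask = largest_central_component(mask)
        if mask.sum() == 0:
            raise DegenerateSegmentationError(
                f"empty mask after postprocessing (k={k_opt:.1f}, "
                f"alpha={alpha_opt:.4f})"
            )
        contour = extract_contour(mask)
        contour_ff = contour + np.array([self.roi.y0, self.roi.x0])

        metrics = None
        if self.truth is not None:
            truth_tci = self.truth[
                self.roi.y0 : self.roi.y1, self.roi.x0 : self.roi.x1
            ]
            metrics = evaluate_masks(truth_tci, mask, n_rays=cfg.n_rays)

        return SegmentationResult(
            k=k_opt,
            alpha=alpha_opt,
            tci=tci,
            partition=partition,
            mask=mask,
            contour=contour,
            contour_fullframe=contour_ff,
            breakdown=breakdown,
            factors=evaluator.factors,
            trace=trace,
            roi=self.roi,
            config=cfg,
            n_evaluations=evaluator.n_evaluations,
            metrics=metrics,
        )


def run_pipeline(
    image: np.ndarray,
    roi: RoiRect | None = None,
    truth: np.ndarray | None = None,
    config: PipelineConfig | None = None,
) -> SegmentationResult:
    """One-call convenience wrapper around SegmentationModel(...).fit()."""
    return SegmentationModel(image, roi=roi, truth=truth, config=config).fit()


# weight triples of the sensitivity experiment, balanced through degenerate
DEFAULT_WEIGHT_GRID = [
    (0.4, 0.3, 0.3), (0.3, 0.4, 0.3), (0.3, 0.3, 0.4),
    (0.6, 0.2, 0.2), (0.2, 0.6, 0.2), (0.2, 0.2, 0.6),
    (0.8, 0.2, 0.2), (0.2, 0.8, 0.2), (0.2, 0.2, 0.8),
    (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0),
]


def weight_sweep(
    items: list[tuple[np.ndarray, np.ndarray]],
    weight_grid: list[tuple[float, float, float]] | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Mean metrics per (a, b, c) weight triple over (image, truth) pairs.

    Probes how the balance between the contrast, uniformity and edge terms
    shifts the segmentation between over- and undersegmentation.
    """
    grid = weight_grid or DEFAULT_WEIGHT_GRID
    base = config or PipelineConfig()
    rows = []
    for a, b, c in grid:
        per_img = []
        for img, truth in items:
            cfg = PipelineConfig.from_dict(
                {**base.to_dict(), "weights": {"a": a, "b": b, "c": c}}
            )
            res = run_pipeline(img, truth=truth, config=cfg)
            per_img.append(res.metrics.to_dict())
        df = pd.DataFrame(per_img)
        rows.append(
            {"a": a, "b": b, "c": c,
             "are": df["are"].mean(), "tpvf": df["tpvf"].mean(),
             "fpvf": df["fpvf"].mean(), "fnvf": df["fnvf"].mean()}
        )
    return pd.DataFrame(rows)
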