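"""End-to-end processing: clouds + plots -> per-plot canopy metrics.

One call runs the full chain for a block and flight date: build the
canopy TIN and the raised soil-reference TIN, compute a per-plot
difference model, sample the 1-cm height field, apply the hard-cap and
SD cleanup, and assemble canopy metrics.  The CLI is a thin wrapper
around :func:`process_block`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import yaml

from .diffmodel import (DifferenceModel, difference_no_breaklines,
                        difference_trace_all_triangles)
from .io import PlotBoundary, PointCloud
from .metrics import (CanopyMetrics, HeightField, compute_metrics,
                      hard_cap_filter, sample_height_field, sd_cleanup)
from .surfaces import RidgeSpec, TINSurface, build_soil_reference, build_tin

log = logging.getLogger(__name__)

DIFF_METHODS = {
    "no_breaklines": difference_no_breaklines,
    "trace_all_triangles": difference_trace_all_triangles,
}


@dataclass
class PipelineConfig:
    """Resolved processing parameters (defaults as documented per stage)."""

    canopy_path: str | None = None
    soil_path: str | None = None
    plots_path: str | None = None
    output_dir: str | None = None
    ridge_height: float | None = None
    crest_lines_path: str | None = None
    resolution: float = 0.01
    hard_cap: float = 1.2
    sd_k: float = 3.0
    diff_method: str = "no_breaklines"
    histogram_bin_width: float = 0.02
    date: str = ""
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PlotResult:
    metrics: CanopyMetrics
    diff: DifferenceModel
    pre_field: HeightField
    cleaned_field: HeightField


def process_block(canopy_cloud: PointCloud, bare_soil_cloud: PointCloud,
                  plots: Sequence[PlotBoundary],
                  ridge: RidgeSpec | float,
                  *,
                  resolution: float = 0.01,
                  hard_cap: float = 1.2,
                  sd_k: float = 3.0,
                  diff_method: str = "no_breaklines",
                  histogram_bin_width: float = 0.02,
                  date: str | float = "") -> list[PlotResult]:
    """Run surfaces -> difference model -> cleanup -> metrics for every plot."""
    if diff_method not in DIFF_METHODS:
        raise ValueError(f"unknown diff_method {diff_method!r}")
    canopy_tin = build_tin(canopy_cloud, kind="canopy")
    soil_ref = build_soil_reference(bare_soil_cloud, ridge,
                                    cloud_for_estimate=canopy_cloud)
    log.info("canopy TIN: %d vertices; soil reference: %d vertices",
             len(canopy_tin.vertices), len(soil_ref.vertices))
    results = []
    for plot in plots:
        try:
            diff = DIFF_METHODS[diff_method](canopy_tin, soil_ref, plot)
            pre = sample_height_field(diff, plot, resolution=resolution)
            capped = hard_cap_filter(pre, cap=hard_cap)
            cleaned = sd_cleanup(capped, k=sd_k) if capped.n_valid >= 2 else capped
            m = compute_metrics(cleaned, diff, pre, date=date,
                                bin_width=histogram_bin_width)
        except Exception as exc:
            raise RuntimeError(f"plot {plot.plot_id!r}: {exc}") from exc
        results.append(PlotResult(metrics=m, diff=diff, pre_field=pre,
                                  cleaned_field=cleaned))
    return results
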