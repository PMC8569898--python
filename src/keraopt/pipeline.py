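"""Pipeline orchestration: configuration, staged execution, report bundle.

The stages mirror the optimization workflow: screen a two-level design for
the salts that matter, fit the second-order response surface to the CCD,
train the tanh network on the same runs, compare the two models, and locate
the constrained optimum of the fitted surface.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import ann, io, metrics, rsm, screening
from .datasets import load_fixture

logger = logging.getLogger("keraopt")

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("screen", "rsm", "ann", "compare", "optimize")


@dataclass
class RunConfig:
    """Configuration for a pipeline run.

    Data can come from embedded fixtures (by name) or from factor/design
    file pairs.  Every omitted field has the default shown; a config
    round-trips through YAML unchanged.
    """

    stages: tuple[str, ...] = _STAGES
    screening_fixture: str | None = None
    screening_factors: str | None = None
    screening_design: str | None = None
    surface_fixture: str | None = None
    surface_factors: str | None = None
    surface_design: str | None = None
    alpha_level: float = 0.05
    ann_config: dict = field(default_factory=dict)
    region: str = "cuboid"
    radius: float = 1.682
    outdir: str | None = None
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {_STAGES}")

    def to_yaml(self) -> str:
        doc = dataclasses.asdict(self)
        doc["stages"] = list(self.stages)
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))


def _load_screening(config: RunConfig):
    if config.screening_fixture:
        design, resp, _ = load_fixture(config.screening_fixture)
        return design, resp
    if config.screening_factors and config.screening_design:
        design, resp = io.read_tables(
            config.screening_factors, config.screening_design, design_kind="plackett_burman"
        )
        if resp is None:
            raise ValueError("screening design file carries no response column")
        return design, resp
    raise ValueError("screen stage needs screening_fixture or factor/design files")


def _load_surface(config: RunConfig):
    if config.surface_fixture:
        design, resp, _ = load_fixture(config.surface_fixture)
        return design, resp
    if config.surface_factors and config.surface_design:
        design, resp = io.read_tables(
            config.surface_factors, config.surface_design, design_kind="ccd"
        )
        if resp is None:
            raise ValueError("surface design file carries no response column")
        return design, resp
    raise ValueError("this stage needs surface_fixture or factor/design files")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the report bundle.

    When ``config.outdir`` is set, JSON and text reports are written there.
    Every reported number is re-derivable by calling the underlying module
    functions directly.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    logger.info("pipeline start; seed=%d stages=%s", config.seed, config.stages)
    bundle: dict = {"config": dataclasses.asdict(config)}
    needs = set(config.stages)
    if "compare" in needs and not {"rsm", "ann"} <= needs:
        raise ValueError("compare stage requires both rsm and ann stages")
    if "optimize" in needs and "rsm" not in needs:
        raise ValueError("optimize stage requires the rsm stage")

    quad_model = None
    surface = None
    predictions: dict = {}

    for stage in config.stages:
        t0 = time.perf_counter()
        if stage == "screen":
            design, resp = _load_screening(config)
            result = screening.analyze_screening(design, resp, config.alpha_level)
            bundle["screening"] = io.screening_report(result)
            bundle["screening"]["pareto"] = {
                name: {"abs_t": float(r["abs_t"]), "significant": bool(r["significant"])}
                for name, r in screening.pareto_ranking(result).iterrows()
            }
        elif stage == "rsm":
            surface = _load_surface(config)
            design, resp = surface
            quad_model = rsm.fit_quadratic(design, resp)
            anova = rsm.anova_quadratic(quad_model, design, resp)
            goodness = rsm.goodness_quadratic(quad_model, design, resp)
            bundle["rsm"] = io.anova_report(quad_model, anova, goodness)
            bundle["rsm"]["uncoded"] = _uncoded_doc(quad_model)
            predictions["RCCD"] = quad_model.predict(design)
        elif stage == "ann":
            if surface is None:
                surface = _load_surface(config)
            design, resp = surface
            cfg = ann.TrainConfig(seed=config.seed, **config.ann_config)
            net, net_metrics = ann.train_network(ann.NetworkSpec(design.n_factors), design, resp, cfg)
            bundle["ann"] = {
                "metrics": {k: dataclasses.asdict(m) for k, m in net_metrics.items()},
                "model": net.to_json(),
            }
            predictions["ANN"] = ann.predict_network(net, design)
        elif stage == "compare":
            design, resp = surface
            report = metrics.compare_models(
                resp.response, predictions, subset=resp.subset
            )
            bundle["compare"] = io.comparison_report(report)
            bundle["compare_text"] = io.format_comparison(report)
        elif stage == "optimize":
            opt = rsm.optimize_response(quad_model, region=config.region, radius=config.radius)
            bundle["optimum"] = {
                "coded": [float(v) for v in opt.coded],
                "actual": None if opt.actual is None else [float(v) for v in opt.actual],
                "predicted_response": opt.predicted_response,
                "on_boundary": opt.on_boundary,
                "region": opt.region,
                "radius": opt.radius,
            }
        logger.info("stage %-8s done in %.2fs", stage, time.perf_counter() - t0)

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        serializable = {k: v for k, v in bundle.items() if k != "compare_text"}
        io.write_json(serializable, out / "report.json")
        if "compare_text" in bundle:
            (out / "comparison.txt").write_text(bundle["compare_text"] + "\n")
        logger.info("reports written to %s", out)
    return bundle


def _uncoded_doc(model) -> dict:
    un = rsm.uncode_model(model)
    return {
        "intercept": un["intercept"],
        "linear": un["linear"],
        "square": un["square"],
        "interaction": {"*".join(k): v for k, v in un["interaction"].items()},
    }
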