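#!/usr/bin/env python
"""Compare the response-surface and neural-network models of AA release.

Computes R2, RMSE, MAD and SSE for training (22 runs), validation (18 runs)
and all 40 runs for both models, the predicted-vs-actual regression per
model, and residual diagnostics for the quadratic fit.  Uses the network
saved by 03_train_network.py (retrains with the same settings if absent).
The quadratic model reaches overall R2 0.983 (RMSE 39.2); the network's
standing depends on the kept restart — see the comparison table printed.
"""

from pathlib import Path

import pandas as pd

from keraopt.ann import MLPModel, NetworkSpec, TrainConfig, predict_network, train_network
from keraopt.datasets import load_fixture
from keraopt.io import comparison_report, format_comparison, write_json
from keraopt.metrics import compare_models, residual_diagnostics
from keraopt.rsm import fit_quadratic

OUT = Path(__file__).resolve().parent.parent / "results"


def ann_predictions(design, responses):
    model_path = OUT / "ann_model.json"
    if model_path.exists():
        net = MLPModel.from_json(model_path.read_text())
    else:
        cfg = TrainConfig(tours=10_000, restarts=20, seed=1)
        net, _ = train_network(NetworkSpec(3, (4, 5)), design, responses, cfg)
    return predict_network(net, design)


def main() -> None:
    design, responses, _ = load_fixture("rccd_table2")
    quad = fit_quadratic(design, responses)
    predictions = {
        "RCCD": quad.predict(design),
        "ANN": ann_predictions(design, responses),
    }
    report = compare_models(responses.response, predictions, subset=responses.subset)
    print(format_comparison(report))

    OUT.mkdir(exist_ok=True)
    write_json(comparison_report(report), OUT / "model_comparison.json")
    (OUT / "model_comparison.txt").write_text(format_comparison(report) + "\n")

    diag = residual_diagnostics(responses.response, predictions["RCCD"])
    diag.to_csv(OUT / "rsm_residual_diagnostics.csv", index=False)
    print(f"\nlargest |residual| of the quadratic fit: {diag['residual'].abs().max():.1f}")
    for label, block in report["models"].items():
        pva = block["pred_vs_actual"]
        print(
            f"predicted-vs-actual [{label}]: slope={pva['slope']:.3f} "
            f"intercept={pva['intercept']:.1f} R2={pva['r2']:.4f}"
        )


if __name__ == "__main__":
    main()
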