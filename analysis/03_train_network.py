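#!/usr/bin/env python
"""Train the tanh regression network on the composite-design runs.

Architecture 3 -> 4 -> 5 -> 1 (tanh hidden layers, linear output), trained
by full-batch gradient descent (rate 0.1, 10,000 tours, squared weight
penalty 0.01 on the standardized scale) using the published 22/18
training/validation split; 20 seeded restarts, keeping the network with the
highest validation R2.  Writes the kept model as JSON plus its predictions,
for reuse by the comparison step.
"""

import json
from pathlib import Path

import pandas as pd

from keraopt.ann import NetworkSpec, TrainConfig, predict_network, train_network
from keraopt.datasets import load_fixture

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    design, responses, _ = load_fixture("rccd_table2")
    cfg = TrainConfig(tours=10_000, learning_rate=0.1, penalty_lambda=0.01,
                      restarts=20, seed=SEED)
    net, metrics = train_network(NetworkSpec(3, (4, 5)), design, responses, cfg)

    print(f"kept network (best validation R2 of {cfg.restarts} restarts, seed {SEED}):")
    for name, m in metrics.items():
        print(f"  {name:<11} n={m.n:<3} R2={m.r2:.4f} RMSE={m.rmse:.3f} MAD={m.mad:.3f}")

    OUT.mkdir(exist_ok=True)
    (OUT / "ann_model.json").write_text(net.to_json())
    pd.DataFrame(
        {
            "run": responses.run_id,
            "observed": responses.response,
            "ann_predicted": predict_network(net, design),
            "subset": responses.subset,
        }
    ).to_csv(OUT / "ann_predictions.csv", index=False)
    (OUT / "ann_metrics.json").write_text(
        json.dumps({k: vars(m) for k, m in metrics.items()}, indent=1) + "\n"
    )
    print(f"wrote {OUT / 'ann_model.json'} and predictions")


if __name__ == "__main__":
    main()
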