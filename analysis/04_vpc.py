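"""Visual predictive checks of the fitted models (500 replicates).

Writes per-bin observed vs simulated percentile tables for the 35 mg rich
study and the 60 mg sparse study under results/vpc/.
"""

import json
from pathlib import Path

import numpy as np

from denopk import dataset_io, diagnostics, estimation

SEED = 20250928
OUT = Path("results/vpc")


def run(name: str, data_path: str, fit_path: str) -> None:
    subjects = dataset_io.read_dataset(data_path)
    subjects, _ = dataset_io.apply_blq_policy_all(subjects)
    model = estimation.model_from_dict(
        json.loads(Path(fit_path).read_text())["model"]
    )
    res = diagnostics.vpc(model, subjects, n_rep=500, seed=SEED)
    diagnostics.vpc_table(res).to_csv(OUT / f"vpc_{name}.csv", index=False)
    ok = res.n_obs_per_bin > 0
    inside = np.mean(
        (res.obs_pct[ok, 1] >= res.sim_pct[ok, 0]) & (res.obs_pct[ok, 1] <= res.sim_pct[ok, 2])
    )
    print(f"{name}: observed median inside simulated 5-95 band in {100 * inside:.0f}% of bins")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    run("35mg", "results/datasets/phase1.csv", "results/fits/phase1_fit.json")
    run("60mg", "results/datasets/phase3.csv", "results/fits/pooled_fit.json")


if __name__ == "__main__":
    main()
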