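"""Fit the one-compartment MM model to the simulated phase-I study and
compare the recovered parameters with the generating values.

Reads results/datasets/phase1.csv (run 01_simulate_trials.py first); a
reduced subject count keeps the fit to a few minutes.  Writes the fit
report (JSON + text table) under results/fits/.
"""

import json
from pathlib import Path

from denopk import dataset_io, estimation

SEED = 20250926
N_SUBJECTS = 153  # subset of the 255 simulated subjects
OUT = Path("results/fits")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    subjects = dataset_io.read_dataset("results/datasets/phase1.csv")[:N_SUBJECTS]
    subjects, blq = dataset_io.apply_blq_policy_all(subjects)
    print(
        f"fitting {len(subjects)} subjects, {sum(s.n_obs for s in subjects)} records "
        f"({blq.n_dropped_trailing} trailing + {blq.n_dropped_intermediate} intermediate "
        f"BLQ dropped, {blq.n_imputed_zero} leading imputed to 0)"
    )
    init = estimation.nca_init(subjects)
    result = estimation.fit(subjects, init, compute_se=True, seed=SEED)
    print(estimation.format_fit_table(result))
    (OUT / "phase1_fit.json").write_text(
        json.dumps(estimation.fit_report(result), indent=2)
    )
    print("shrinkage %:", {k: round(v, 1) for k, v in result.eta_shrinkage_pct.items()})


if __name__ == "__main__":
    main()
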