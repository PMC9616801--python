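#!/usr/bin/env python
"""Generate the synthetic sessions used by the downstream analysis scripts.

Writes three sessions under results/sessions/: the default study-condition
session (static silencing-effect pattern), a rotating-effect variant
(adjacent-window effect cosine 0.2), and a small multi-animal cohort for
the null-simulation comparison.  Ground truth is saved alongside.
"""

import argparse
from pathlib import Path

from commdyn.io import save_ground_truth, save_session
from commdyn.simulate import SimConfig, simulate_session

OUT = Path("results/sessions")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    configs = {
        "static": SimConfig(seed=args.seed),
        "rotating": SimConfig(seed=args.seed, silencing_effect_mode="rotating",
                              effect_rotation_cos_per_lag=0.2),
    }
    for animal in range(10):
        configs[f"cohort_{animal:02d}"] = SimConfig(
            seed=args.seed + 100 + animal, silencing_effect_mode="rotating",
            effect_rotation_cos_per_lag=0.2, n_source=15, n_target=20,
            n_control=60, n_silencing_per_window=40,
        )

    for name, cfg in configs.items():
        session, truth = simulate_session(cfg)
        save_session(session, OUT / f"{name}.h5")
        save_ground_truth(truth, OUT / f"{name}.truth.json")
        print(f"{name}: {session.n_trials} trials, {session.n_neurons} neurons, "
              f"{session.spike_time.size} spikes")


if __name__ == "__main__":
    main()
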