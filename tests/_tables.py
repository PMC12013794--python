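"""Shared synthetic metric tables for the statistics tests."""

import numpy as np
import pandas as pd


def plateau_table(seed, effect=-2.0, n_part=12, n_trials=4,
                  part_sd=0.5, noise_sd=0.7):
    """Long-format table with a built-in plateau-two rate effect."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_part):
        b = rng.normal(0, part_sd)
        for tr in range(n_trials):
            for plat, eff in (("one", 0.0), ("two", effect)):
                rows.append({"participant": p, "trial": tr, "plateau": plat,
                             "muscle": "TA" if tr % 2 else "MG",
                             "rate": 12 + b + eff + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)
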