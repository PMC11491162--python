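"""Deterministic toy study generator used by the CLI docs and the test suite.

Small enough for CI: a handful of samples, a few ROIs each, two phenotypes
("tumor", "immune") scattered in rectangular windows, plus a matching
outcome table.  Everything derives from a single seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import OutcomeTable, PointPattern, Window

__all__ = ["toy_study"]


def toy_study(
    n_samples: int = 12,
    rois_per_sample: int = 3,
    seed: int = 0,
    outcome: str = "survival",
    cluster_scale: float = 8.0,
):
    """Return (patterns, outcome_table) for a small synthetic study.

    Tumor cells are laid down as a parent-offspring cluster process (so K
    shows clustering); immune cells are uniform.  The survival (or binary)
    outcome is mildly associated with the per-sample cluster tightness.
    """
    if outcome not in {"survival", "binary"}:
        raise ValueError("outcome must be 'survival' or 'binary'")
    rng = np.random.default_rng(seed)
    patterns = []
    tightness = rng.uniform(0.5, 1.5, size=n_samples)
    for i in range(n_samples):
        sid = f"S{i:02d}"
        for r in range(rois_per_sample):
            win = Window(0.0, 400.0, 0.0, 300.0)
            n_parents = rng.poisson(6) + 2
            px = rng.uniform(0, 400, n_parents)
            py = rng.uniform(0, 300, n_parents)
            per = rng.poisson(6, n_parents) + 2
            tx = np.repeat(px, per) + rng.normal(
                0, cluster_scale * tightness[i], per.sum()
            )
            ty = np.repeat(py, per) + rng.normal(
                0, cluster_scale * tightness[i], per.sum()
            )
            tx = np.clip(tx, 0, 400)
            ty = np.clip(ty, 0, 300)
            n_imm = rng.poisson(40) + 5
            ix = rng.uniform(0, 400, n_imm)
            iy = rng.uniform(0, 300, n_imm)
            patterns.append(
                PointPattern(
                    x=np.concatenate([tx, ix]),
                    y=np.concatenate([ty, iy]),
                    marks=np.array(["tumor"] * len(tx) + ["immune"] * n_imm),
                    window=win,
                    sample_id=sid,
                    roi_id=f"R{r}",
                )
            )
    ids = [f"S{i:02d}" for i in range(n_samples)]
    age = rng.uniform(40, 80, n_samples).round(1)
    if outcome == "survival":
        times = rng.exponential(scale=np.exp(tightness - 1))
        df = pd.DataFrame(
            {
                "sample_id": ids,
                "time": times.round(4),
                "event": np.ones(n_samples, dtype=int),
                "age": age,
            }
        )
    else:
        labels = (tightness + rng.normal(0, 0.3, n_samples) > 1.0).astype(int)
        df = pd.DataFrame({"sample_id": ids, "label": labels, "age": age})
    return patterns, OutcomeTable(df)
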