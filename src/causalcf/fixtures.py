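"""Small deterministic fixture datasets used in tests and examples.

All fixtures are generated programmatically (synthetic data only) and a
manifest of SHA-256 checksums makes regeneration verifiable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import presets
from .dgm import simulate_dataset


def _aipw_oracle_table(seed: int) -> pd.DataFrame:
    """Six records with randomized (Y, X, e1, e0, g) for term-by-term
    verification of the one-step estimator."""
    rng = np.random.default_rng(seed)
    n = 6
    return pd.DataFrame({
        "y": rng.normal(size=n).round(4),
        "x": rng.integers(0, 2, size=n),
        "e1": rng.normal(size=n).round(4),
        "e0": rng.normal(size=n).round(4),
        "g": rng.uniform(0.2, 0.8, size=n).round(4),
    })


def _linear_noiseless(seed: int, reps_per_cell: int = 5) -> pd.DataFrame:
    """Outcome exactly linear in (X, W) with no noise, over binary
    confounders with every (x, w) cell realized: a fitted GLM has zero
    residuals and every counterfactual prediction equals an observed cell
    mean (inside the outcome range), so the one-step and targeted
    estimators coincide with g-computation."""
    rng = np.random.default_rng(seed)
    cells = [(x, w1, w2) for x in (0, 1) for w1 in (0, 1) for w2 in (0, 1)]
    rows = cells * reps_per_cell
    order = rng.permutation(len(rows))
    x, w1, w2 = (np.array([rows[i][k] for i in order], dtype=float)
                 for k in range(3))
    y = 1.0 + 0.7 * x + 0.5 * w1 - 0.3 * w2
    return pd.DataFrame({"y": y, "x": x.astype(int),
                         "w1": w1.astype(int), "w2": w2.astype(int)})


def _demo_dataset(seed: int, n: int = 300) -> pd.DataFrame:
    params = presets.calibrated_params("simple-1", 500)
    return simulate_dataset(params, n, seed).to_frame().round(6)


def make_fixtures(out_dir, seed: int = 20_240_901) -> dict[str, str]:
    """Write the packaged fixture CSVs and a checksum manifest.

    Regeneration with the same seed is idempotent (byte-identical files).
    Returns the name -> sha256 mapping.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "aipw_oracle_6rec.csv": _aipw_oracle_table(seed),
        "linear_noiseless.csv": _linear_noiseless(seed + 1),
        "demo_simple1_n300.csv": _demo_dataset(seed + 4),
    }
    manifest = {}
    for name, df in tables.items():
        path = out / name
        df.to_csv(path, index=False, lineterminator="\n")
        manifest[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def load_manifest(out_dir) -> dict[str, str]:
    with open(Path(out_dir) / "manifest.json") as fh:
        return json.load(fh)
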