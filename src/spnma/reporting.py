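"""Side-by-side model comparison tables and reproducible run manifests."""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from .inference import PosteriorSummary
from .simulation import ScenarioSpec

__all__ = ["report_comparison", "intervals_disjoint", "run_manifest", "write_manifest"]


def intervals_disjoint(lo_a, hi_a, lo_b, hi_b) -> bool:
    """Closed-interval test: touching endpoints count as overlapping."""
    return bool(hi_a < lo_b or hi_b < lo_a)


def report_comparison(
    summary_a: PosteriorSummary,
    summary_b: PosteriorSummary,
    truth: ScenarioSpec | None = None,
) -> pd.DataFrame:
    """Merge two fitted summaries into one ratio-scale comparison table.

    Both summaries must cover the same (treatment, outcome) grid.  Each row
    carries the two means and 95% credible intervals plus ``disjoint_cri``,
    flagging cells whose intervals do not overlap (the shading rule of the
    constructed-data experiment).  With a ``truth`` scenario, a column of
    true ratios is added for simulation runs.  The table doubles as
    forest-plot input: one row per point-and-interval pair.
    """
    cols = ["treatment", "outcome", "hr_mean", "hr_q2.5", "hr_q97.5"]
    a = summary_a.hr_table[cols].rename(
        columns={c: f"{c}_a" for c in cols[2:]}
    )
    b = summary_b.hr_table[cols].rename(
        columns={c: f"{c}_b" for c in cols[2:]}
    )
    merged = a.merge(b, on=["treatment", "outcome"], how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        raise ValueError("summaries do not cover the same (treatment, outcome) grid")
    merged = merged.drop(columns="_merge")
    merged["model_a"] = summary_a.model
    merged["model_b"] = summary_b.model
    merged["disjoint_cri"] = [
        intervals_disjoint(r["hr_q2.5_a"], r["hr_q97.5_a"], r["hr_q2.5_b"], r["hr_q97.5_b"])
        for _, r in merged.iterrows()
    ]
    if truth is not None:
        merged["true_ratio"] = [
            float(np.exp(truth.true_effects[int(r["treatment"]) - 1, int(r["outcome"]) - 1]))
            for _, r in merged.iterrows()
        ]
    return merged


def run_manifest(config: dict, seeds: dict, versions: dict | None = None) -> dict:
    """Provenance record for a run: config (hashed), seeds, versions.

    Deterministic by construction — identical inputs give a byte-identical
    JSON serialization, and the manifest round-trips through
    :func:`json.loads` to reproduce the run.  A missing seed is an error.
    """
    if not seeds:
        raise ValueError("a run manifest requires at least one seed")
    for name, value in seeds.items():
        if value is None:
            raise ValueError(f"seed {name!r} is missing")
    canonical = json.dumps(config, sort_keys=True, default=str)
    return {
        "config": json.loads(canonical),
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seeds": dict(sorted(seeds.items())),
        "versions": dict(sorted((versions or {}).items())),
    }


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")
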