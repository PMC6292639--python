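"""File I/O and run configuration for the command-line workflow."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import OrdinalMisclassResults
from .pedigree import Pedigree, _sniff_table

__all__ = ["read_phenotypes", "read_config", "write_outputs", "config_hash"]


def read_phenotypes(
    path,
    pedigree: Pedigree,
    *,
    n_categories: int = 3,
    one_based_classes: bool = False,
) -> pd.DataFrame:
    """Read and validate a phenotype table.

    Expected columns (header required): an animal ID column first, one or
    more systematic-effect level columns, and the observed ordinal class
    last.  Classes are 0-based by default; ``one_based_classes`` shifts
    1..C input down.  Raises on classes outside 0..C-1 or animals missing
    from the pedigree.
    """
    df = _sniff_table(path)
    if df.shape[1] < 3:
        raise ValueError("phenotype file needs >= 3 columns (animal, effects, class)")
    df = df.rename(
        columns={df.columns[0]: "animal", df.columns[-1]: "response"}
    )
    if one_based_classes:
        df["response"] = df["response"] - 1
    y = df["response"].to_numpy()
    if y.min() < 0 or y.max() >= n_categories:
        raise ValueError(
            f"observed class outside 0..{n_categories - 1}: found {y.min()}..{y.max()}"
        )
    known = set(pedigree.original_ids.tolist())
    missing = set(df["animal"]) - known
    if missing:
        raise ValueError(f"animal {sorted(missing)[0]!r} not in pedigree")
    for col in df.columns[1:-1]:
        if df[col].nunique() < 1:
            raise ValueError(f"effect column {col} is empty")
    return df


def read_config(path) -> dict:
    """Load a YAML (or JSON) key-value run configuration."""
    text = Path(path).read_text()
    return yaml.safe_load(text) or {}


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_outputs(results: OrdinalMisclassResults, outdir, *, seed: int,
                  config: dict | None = None) -> dict:
    """Write samples.tsv, ebv.tsv, misclass.tsv and summary.json.

    Every file is reproducible from (config, seed); summary.json embeds both
    along with a hash of the configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or {}

    samples = pd.DataFrame(
        {
            "draw": np.arange(results.n_retained),
            "sigma_u2": results.sigma_u2_samples,
            "t1": results.t1_samples,
            "h2": results.h2_samples,
        }
    )
    samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    results.ebv.reset_index().to_csv(outdir / "ebv.tsv", sep="\t", index=False)
    results.misclass.to_csv(outdir / "misclass.tsv", sep="\t", index=False)

    summary = {
        "seed": int(seed),
        "config": config,
        "config_hash": config_hash(config),
        "n_records": int(results.model.nobs),
        "n_pedigree": int(results.model.pedigree.n_animals),
        "n_retained": int(results.n_retained),
        "parameters": {
            name: dict(row) for name, row in results.summary().iterrows()
        },
        "pi_mean": results.pi.to_numpy().tolist(),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
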