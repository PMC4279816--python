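"""Consolidated report bundle: per-stage tables + run metadata."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__


def config_hash(config_dict: dict) -> str:
    """Stable hash of a canonicalized config mapping."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_report(out_dir, sections: dict, config_dict: dict, seed) -> dict:
    """Write ``report.json`` plus one TSV per tabular section entry.

    ``sections`` maps section name -> dict of scalars / nested dicts /
    DataFrames.  DataFrames are written as ``<section>_<key>.tsv`` and
    referenced by filename in the JSON.  Stage metadata carrying a ``seed``
    that disagrees with the run seed is an error (conflicting provenance).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = {
        "metadata": {
            "package_version": __version__,
            "seed": seed,
            "config_hash": config_hash(config_dict),
            "config": config_dict,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
        "sections": {},
    }
    for name, content in sections.items():
        if content is None:
            doc["sections"][name] = {"status": "absent"}
            continue
        stage_seed = content.get("seed") if isinstance(content, dict) else None
        if stage_seed is not None and seed is not None and stage_seed != seed:
            raise ValueError(
                f"conflicting run metadata: stage {name!r} seed {stage_seed} != run seed {seed}"
            )
        rendered = {"status": "present"}
        for key, val in content.items():
            if isinstance(val, pd.DataFrame):
                fname = f"{name}_{key}.tsv"
                val.to_csv(out / fname, sep="\t", index=val.index.name is not None)
                rendered[key] = {"table": fname}
            else:
                rendered[key] = val
        doc["sections"][name] = rendered
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=str)
    return doc
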